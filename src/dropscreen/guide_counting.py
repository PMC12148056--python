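"""Guide quantification from amplicon FASTQ reads.

The amplicon places a variable 0-7 nt stagger (from the phased forward
primers) before a constant vector anchor, immediately followed by the 20-nt
protospacer.  A read is assigned by locating the anchor at offsets
0..max_stagger and exact-matching the following 20-mer against the library;
anything else is counted as unassigned.  Exact matching (zero mismatches,
hash lookup) is the declared convention — unambiguous and standard for
screen counting.  Reverse-complement search is off by default because the
amplicon orientation is fixed by the primer design.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library_model import GuideLibrary
from .synthetic_data import ANCHOR

DEFAULT_ANCHOR = ANCHOR


@dataclass
class CountMatrix:
    """guide x sample integer counts, plus per-sample unassigned reads."""

    counts: pd.DataFrame        # index guide_id, one column per sample
    unassigned: pd.Series       # per-sample unassigned reads

    @property
    def totals(self) -> pd.Series:
        """Total input reads per sample (assigned + unassigned)."""
        return self.counts.sum(axis=0) + self.unassigned

    @property
    def assignment_rate(self) -> pd.Series:
        totals = self.totals
        return (self.counts.sum(axis=0) / totals.where(totals > 0)).fillna(0.0)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "guide_id"
        out.to_csv(path, sep="\t")

    def summary(self) -> dict:
        return {
            "samples": {
                s: {
                    "total_reads": int(self.totals[s]),
                    "assigned": int(self.counts[s].sum()),
                    "unassigned": int(self.unassigned[s]),
                    "assignment_rate": float(self.assignment_rate[s]),
                }
                for s in self.counts.columns
            }
        }

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a count table (TSV or CSV; first column guide_id)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def extract_guide(
    read_sequence: str,
    anchor: str = DEFAULT_ANCHOR,
    max_stagger: int = 7,
) -> str | None:
    """Return the 20-mer following the anchor, or None if unassignable.

    The anchor is searched at offsets 0..max_stagger only; the first exact
    match wins.  No-assignment is a value, not an error.
    """
    la = len(anchor)
    for offset in range(max_stagger + 1):
        if read_sequence.startswith(anchor, offset):
            start = offset + la
            if len(read_sequence) >= start + 20:
                return read_sequence[start : start + 20]
            return None
    return None


def _open_text(path: str | Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def count_guides(
    fastq_by_sample: Mapping[str, str | Path | Sequence[str | Path]],
    lib: GuideLibrary,
    anchor: str = DEFAULT_ANCHOR,
    max_stagger: int = 7,
    search_reverse_complement: bool = False,
) -> CountMatrix:
    """Count guide-assigned reads per sample from FASTQ files.

    ``fastq_by_sample`` maps sample name to one path or a list of paths.
    Every library guide keeps a row (zeros retained); assigned + unassigned
    equals the number of input reads for each sample.
    """
    lookup = {g.protospacer: i for i, g in enumerate(lib.guides)}
    samples = list(fastq_by_sample)
    counts = np.zeros((len(lib), len(samples)), dtype=np.int64)
    unassigned = np.zeros(len(samples), dtype=np.int64)
    for j, sample in enumerate(samples):
        paths = fastq_by_sample[sample]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        for path in paths:
            record_idx = 0
            try:
                with _open_text(path) as fh:
                    for _title, seq, _qual in FastqGeneralIterator(fh):
                        record_idx += 1
                        proto = extract_guide(seq.upper(), anchor, max_stagger)
                        if proto is None and search_reverse_complement:
                            proto = extract_guide(
                                reverse_complement(seq.upper()), anchor, max_stagger
                            )
                        row = lookup.get(proto) if proto is not None else None
                        if row is None:
                            unassigned[j] += 1
                        else:
                            counts[row, j] += 1
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ near record {record_idx + 1}: {exc}"
                ) from exc
    return CountMatrix(
        counts=pd.DataFrame(counts, index=lib.guide_ids, columns=samples),
        unassigned=pd.Series(unassigned, index=samples),
    )
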