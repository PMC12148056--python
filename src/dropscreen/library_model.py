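"""sgRNA library representation and quality control.

A pooled knockout library is a catalog of single-guide RNAs (sgRNAs), each
identified by a unique 20-nt protospacer and mapped to a target gene; a block
of non-targeting guides (gene ``NON_TARGETING``) provides a null reference.
The default generator builds a Brie-style library: a genome-wide mouse
knockout library with up to four guides per gene plus 1,000 non-targeting
controls (78,637 guides in total over 19,674 genes).

Representation quality is summarized by the Gini coefficient of the guide
count distribution (0 = perfectly even) and by coverage (fraction of guides
seen at least once at a given sequencing depth).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

NON_TARGETING = "NON_TARGETING"

_BASES = np.array(["A", "C", "G", "T"])

# Brie library composition: 19,674 genes, <=4 guides each, 1,000 controls,
# 78,637 guides total.  4*19,674 + 1,000 = 79,696, so 1,059 genes carry only
# 3 guides to reproduce the printed total.
BRIE_N_GENES = 19_674
BRIE_N_NONTARGETING = 1_000
BRIE_TOTAL_GUIDES = 78_637


@dataclass(frozen=True)
class Guide:
    """A single sgRNA: id, target gene (or NON_TARGETING), 20-nt protospacer."""

    guide_id: str
    target_gene: str
    protospacer: str

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError(
                f"protospacer of {self.guide_id!r} has length "
                f"{len(self.protospacer)}, expected 20"
            )
        if set(self.protospacer) - set("ACGT"):
            raise ValueError(
                f"protospacer of {self.guide_id!r} contains non-ACGT characters"
            )

    @property
    def is_nontargeting(self) -> bool:
        return self.target_gene == NON_TARGETING


@dataclass
class GuideLibrary:
    """Ordered collection of guides with optional plasmid abundance weights."""

    guides: list[Guide]
    abundance: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = [g.guide_id for g in self.guides]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate guide_id in library")
        seqs = [g.protospacer for g in self.guides]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate protospacer in library")
        if self.abundance is not None:
            self.abundance = np.asarray(self.abundance, dtype=float)
            if self.abundance.shape != (len(self.guides),):
                raise ValueError("abundance must have one entry per guide")
            if np.any(self.abundance < 0) or self.abundance.sum() <= 0:
                raise ValueError("abundance must be nonnegative with positive sum")

    def __len__(self) -> int:
        return len(self.guides)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GuideLibrary):
            return NotImplemented
        same_guides = self.guides == other.guides
        if self.abundance is None or other.abundance is None:
            return same_guides and (self.abundance is None) == (other.abundance is None)
        return same_guides and np.array_equal(self.abundance, other.abundance)

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    @property
    def genes(self) -> list[str]:
        """Distinct target genes (non-targeting excluded), in first-seen order."""
        seen: dict[str, None] = {}
        for g in self.guides:
            if not g.is_nontargeting:
                seen.setdefault(g.target_gene, None)
        return list(seen)

    @property
    def gene_by_guide(self) -> dict[str, str]:
        return {g.guide_id: g.target_gene for g in self.guides}

    def abundance_probabilities(self) -> np.ndarray:
        """Guide sampling probabilities (uniform when no abundance is set)."""
        if self.abundance is None:
            return np.full(len(self), 1.0 / len(self))
        return self.abundance / self.abundance.sum()


@dataclass
class LibraryQCReport:
    """Representation QC: Gini coefficient and detection coverage."""

    gini: float
    n_guides_total: int
    n_guides_detected: int
    coverage_fraction: float
    total_reads: int

    def to_dict(self) -> dict:
        return {
            "gini": self.gini,
            "n_guides_total": self.n_guides_total,
            "n_guides_detected": self.n_guides_detected,
            "coverage_fraction": self.coverage_fraction,
            "total_reads": self.total_reads,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _random_protospacers(n: int, rng: np.random.Generator) -> list[str]:
    """n unique random 20-mers, seed-reproducible (rejection on duplicates)."""
    if n > 4**20:
        raise ValueError("cannot draw more unique 20-mers than 4^20")
    powers = 4 ** np.arange(20, dtype=np.int64)
    codes: dict[int, np.ndarray] = {}
    while len(codes) < n:
        batch = rng.integers(0, 4, size=(n - len(codes), 20))
        keys = batch @ powers
        for key, row in zip(keys, batch):
            if int(key) not in codes:
                codes[int(key)] = row
    rows = list(codes.values())[:n]
    return ["".join(_BASES[row]) for row in rows]


def brie_composition(
    n_genes: int = BRIE_N_GENES,
    guides_per_gene: int = 4,
    n_nontargeting: int = BRIE_N_NONTARGETING,
    total_guides: int = BRIE_TOTAL_GUIDES,
) -> np.ndarray:
    """Per-gene guide counts reproducing the Brie library's printed total.

    Assigns ``guides_per_gene`` guides to every gene, then trims one guide
    from the last ``deficit`` genes so that targeting + non-targeting guides
    sum to ``total_guides``.
    """
    deficit = n_genes * guides_per_gene + n_nontargeting - total_guides
    if deficit < 0 or deficit > n_genes:
        raise ValueError("requested totals are not representable")
    counts = np.full(n_genes, guides_per_gene, dtype=int)
    if deficit:
        counts[-deficit:] -= 1
    return counts


def build_default_library(
    n_genes: int,
    guides_per_gene: int = 4,
    n_nontargeting: int = 0,
    seed: int = 0,
    guides_per_gene_vector: Sequence[int] | None = None,
) -> GuideLibrary:
    """Build a synthetic library with random unique protospacers.

    Gene symbols are synthetic ("G000001", ...).  ``guides_per_gene_vector``
    overrides the uniform per-gene count (e.g. the output of
    :func:`brie_composition`).
    """
    if n_genes < 1 or guides_per_gene < 1 or n_nontargeting < 0:
        raise ValueError("invalid library dimensions")
    if guides_per_gene_vector is None:
        per_gene = np.full(n_genes, guides_per_gene, dtype=int)
    else:
        per_gene = np.asarray(guides_per_gene_vector, dtype=int)
        if per_gene.shape != (n_genes,) or np.any(per_gene < 1):
            raise ValueError("guides_per_gene_vector must give >=1 guide per gene")
    n_total = int(per_gene.sum()) + n_nontargeting
    rng = np.random.default_rng(seed)
    seqs = _random_protospacers(n_total, rng)
    guides: list[Guide] = []
    i = 0
    for gi, count in enumerate(per_gene):
        gene = f"G{gi + 1:06d}"
        for j in range(count):
            guides.append(Guide(f"{gene}_sg{j + 1}", gene, seqs[i]))
            i += 1
    for j in range(n_nontargeting):
        guides.append(Guide(f"NT_sg{j + 1}", NON_TARGETING, seqs[i]))
        i += 1
    return GuideLibrary(guides)


def build_brie_library(seed: int = 0) -> GuideLibrary:
    """Full-scale Brie-style library (78,637 guides)."""
    return build_default_library(
        BRIE_N_GENES,
        n_nontargeting=BRIE_N_NONTARGETING,
        seed=seed,
        guides_per_gene_vector=brie_composition(),
    )


def gini_coefficient(counts: Sequence[float] | np.ndarray) -> float:
    """Gini coefficient: mean absolute pairwise difference / (2 * mean).

    0 for perfectly uniform counts; invariant to scaling.  Undefined (error)
    for an all-zero vector.
    """
    x = np.sort(np.asarray(counts, dtype=float))
    if x.size == 0 or np.any(x < 0):
        raise ValueError("counts must be a nonempty nonnegative vector")
    total = x.sum()
    if total == 0:
        raise ValueError("Gini coefficient is undefined for an all-zero vector")
    n = x.size
    # Sorted-vector identity for sum_{i,j} |x_i - x_j|.
    i = np.arange(1, n + 1)
    return float((2.0 * np.sum(i * x)) / (n * total) - (n + 1) / n)


def coverage_stats(counts: Sequence[float] | np.ndarray) -> LibraryQCReport:
    """Detection coverage and Gini of a per-guide read count vector."""
    x = np.asarray(counts)
    detected = int(np.count_nonzero(x >= 1))
    return LibraryQCReport(
        gini=gini_coefficient(x),
        n_guides_total=int(x.size),
        n_guides_detected=detected,
        coverage_fraction=detected / x.size,
        total_reads=int(x.sum()),
    )


def write_library(lib: GuideLibrary, path: str | Path) -> None:
    """Write the 3-column TSV dialect: guide_id, gene, sequence."""
    with open(path, "w", newline="\n") as fh:
        fh.write("guide_id\tgene\tsequence\n")
        for g in lib.guides:
            fh.write(f"{g.guide_id}\t{g.target_gene}\t{g.protospacer}\n")


def read_library(path: str | Path) -> GuideLibrary:
    """Read a library TSV, validating uniqueness and sequence format.

    Errors name the offending line (1-based, including the header).
    """
    guides: list[Guide] = []
    seen_ids: set[str] = set()
    seen_seqs: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["guide_id", "gene", "sequence"]:
            raise ValueError(f"{path}: line 1: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            gid, gene, seq = fields
            try:
                guide = Guide(gid, gene, seq)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if gid in seen_ids:
                raise ValueError(f"{path}: line {lineno}: duplicate guide_id {gid!r}")
            if seq in seen_seqs:
                raise ValueError(f"{path}: line {lineno}: duplicate protospacer {seq!r}")
            seen_ids.add(gid)
            seen_seqs.add(seq)
            guides.append(guide)
    return GuideLibrary(guides)
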