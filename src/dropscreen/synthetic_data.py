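"""Synthetic inputs with known ground truth for the screen pipeline.

Emulates the data-generating process of a pooled in vivo CRISPR knockout
screen in degenerating rod photoreceptors:

* a degeneration trajectory calibrated so that photoreceptor survival is
  ~74% of wild type at 1 month and ~38% at 4 months (piecewise-exponential,
  i.e. constant hazard between anchors);
* per-gene knockout effects expressed as hazard multipliers (>1: knockout
  accelerates death, the gene is neuroprotective and its guides drop out;
  <1: knockout slows death, guides become enriched);
* per-retina screens: cells are infected at a Poisson multiplicity set by
  the regional labeling fraction, each virus delivers one guide drawn from
  the library abundance, cells survive to harvest with probability
  survival^(product of guide multipliers) — with every multiplier forced to
  1 in the Cas9-negative arm — and surviving guide cassettes are sequenced
  by multinomial sampling to a fixed read depth;
* amplicon reads with the nested-PCR staggered-primer structure (0-7 random
  stagger bases, then the constant vector anchor, then the 20-nt
  protospacer, then scaffold filler);
* phenotype signals: ERG traces, PLR intensity-response series on a
  half-log grid from 10^0 to 10^5, and visual-cliff trial outcomes.

All generators take explicit integer seeds; no global RNG state is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .library_model import NON_TARGETING, GuideLibrary
from .moi_design import moi_from_fraction
from .phenotype_analysis import ERGTrace

# Constant vector sequence between the staggered primer bases and the
# protospacer in the sequenced amplicon.
ANCHOR = "TTGTGGAAAGGACGAAACACCG"
# sgRNA scaffold immediately downstream of the protospacer (read filler).
SCAFFOLD = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"

_BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Degeneration trajectory


@dataclass(frozen=True)
class DegenerationModel:
    """Survival fraction (relative ONL thickness) vs age, in months.

    Piecewise-exponential interpolation through calibration anchors: the
    hazard is constant within each inter-anchor interval, so survival is
    log-linear there and composes multiplicatively with knockout hazard
    multipliers.  Default anchors: full thickness at P15 (0.5 mo), 74% of
    WT at 1 month, 38% at 4 months; the last interval's hazard is used for
    extrapolation beyond the final anchor.
    """

    anchor_times: tuple[float, ...] = (0.5, 1.0, 4.0)
    anchor_survival: tuple[float, ...] = (1.0, 0.74, 0.38)

    def __post_init__(self) -> None:
        t = np.asarray(self.anchor_times)
        s = np.asarray(self.anchor_survival)
        if t.size != s.size or t.size < 2:
            raise ValueError("need >= 2 matched anchors")
        if np.any(np.diff(t) <= 0):
            raise ValueError("anchor times must be strictly increasing")
        if np.any(s <= 0) or np.any(s > 1) or np.any(np.diff(s) > 0):
            raise ValueError("anchor survival must be non-increasing in (0, 1]")


def survival_fraction(model: DegenerationModel, t: float) -> float:
    """Surviving fraction at age t months (1.0 at or before the first anchor)."""
    if t < 0:
        raise ValueError("age must be nonnegative")
    times = np.asarray(model.anchor_times)
    logs = np.log(np.asarray(model.anchor_survival))
    if t <= times[0]:
        return 1.0
    # log-linear interpolation; slope of the last interval extrapolates.
    if t >= times[-1]:
        rate = (logs[-1] - logs[-2]) / (times[-1] - times[-2])
        return float(np.exp(logs[-1] + rate * (t - times[-1])))
    return float(np.exp(np.interp(t, times, logs)))


# ---------------------------------------------------------------------------
# Library representation skew


def lognormal_abundance(
    n_guides: int, sigma: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Per-guide plasmid abundance weights with lognormal skew.

    The standard model for plasmid-pool representation skew; sigma=0.5 gives
    a Gini coefficient around 0.28, a realistic well-maintained library.
    """
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=0.0, sigma=sigma, size=n_guides)


def skewed_library(lib: GuideLibrary, sigma: float = 0.5, seed: int = 0) -> GuideLibrary:
    """Copy of ``lib`` carrying lognormal abundance weights."""
    return GuideLibrary(
        list(lib.guides), lognormal_abundance(len(lib), sigma=sigma, seed=seed)
    )


# ---------------------------------------------------------------------------
# Gene effects


@dataclass
class GeneEffectProfile:
    """Hazard multiplier per gene (1 = neutral) with class labels.

    Non-targeting controls always carry multiplier 1.
    """

    multipliers: dict[str, float]

    def __post_init__(self) -> None:
        self.multipliers = dict(self.multipliers)
        self.multipliers[NON_TARGETING] = 1.0
        if any(v <= 0 for v in self.multipliers.values()):
            raise ValueError("hazard multipliers must be positive")

    def multiplier(self, gene: str) -> float:
        return self.multipliers.get(gene, 1.0)

    def label(self, gene: str) -> str:
        m = self.multiplier(gene)
        if m > 1.0:
            return "neuroprotective"
        if m < 1.0:
            return "disease_promoting"
        return "neutral"

    @classmethod
    def neutral(cls, genes: Sequence[str]) -> "GeneEffectProfile":
        return cls({g: 1.0 for g in genes})

    @classmethod
    def planted(
        cls,
        genes: Sequence[str],
        frac_depleted: float = 0.05,
        depleted_multiplier: float = 3.0,
        frac_enriched: float = 0.0,
        enriched_multiplier: float = 0.33,
        seed: int = 0,
    ) -> "GeneEffectProfile":
        """Assign effect classes to random gene subsets (ground truth kept)."""
        if frac_depleted + frac_enriched > 1.0:
            raise ValueError("effect fractions exceed 1")
        rng = np.random.default_rng(seed)
        genes = list(genes)
        n_dep = int(round(frac_depleted * len(genes)))
        n_enr = int(round(frac_enriched * len(genes)))
        order = rng.permutation(len(genes))
        mult = {g: 1.0 for g in genes}
        for i in order[:n_dep]:
            mult[genes[i]] = depleted_multiplier
        for i in order[n_dep : n_dep + n_enr]:
            mult[genes[i]] = enriched_multiplier
        return cls(mult)

    def genes_with_label(self, label: str) -> list[str]:
        return [
            g
            for g in self.multipliers
            if g != NON_TARGETING and self.label(g) == label
        ]

    def write_truth(self, path: str | Path) -> None:
        """Ground-truth sidecar TSV: gene, true multiplier, class label."""
        with open(path, "w", newline="\n") as fh:
            fh.write("gene\tmultiplier\tlabel\n")
            for g, m in self.multipliers.items():
                if g != NON_TARGETING:
                    fh.write(f"{g}\t{m}\t{self.label(g)}\n")


# ---------------------------------------------------------------------------
# Screen simulation


@dataclass
class ScreenExperiment:
    """Simulated screen arm: per-guide harvest cell counts and read counts."""

    library: GuideLibrary
    arm: str  # "cas9_pos" | "cas9_neg"
    sample_names: list[str]
    cell_counts: np.ndarray  # guides x samples, cells at harvest
    read_counts: np.ndarray  # guides x samples, sequenced reads
    n_cells_infected: int
    seed: int

    def counts_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.read_counts, index=self.library.guide_ids, columns=self.sample_names
        )


def _simulate_arm_sample(
    lib: GuideLibrary,
    multipliers: np.ndarray,
    moi_f: float,
    n_cells: int,
    survival: float,
    depth: int,
    rng: np.random.Generator,
    pcr_dispersion: float | None,
    max_k: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """One retina: (cells at harvest, reads) per guide.

    n_cells is the number of infected cells; multiplicities follow the
    zero-truncated Poisson implied by the labeling fraction.  A cell with
    guides g1..gk survives with probability survival^(prod multipliers), and
    every guide cassette of a surviving cell is available for sequencing.
    """
    n_guides = len(lib)
    p_guide = lib.abundance_probabilities()
    m = moi_from_fraction(moi_f)
    if m == 0.0:
        k_probs = np.zeros(max_k)
        k_probs[0] = 1.0
    else:
        k = np.arange(1, max_k + 1)
        from scipy.special import gammaln

        logp = k * np.log(m) - gammaln(k + 1) - m
        k_probs = np.exp(logp)
        k_probs /= k_probs.sum()  # condition on k >= 1
    cells_by_k = rng.multinomial(n_cells, k_probs)

    harvest = np.zeros(n_guides, dtype=np.int64)
    # Single-infected cells: fully vectorized per guide.
    n1 = int(cells_by_k[0])
    if n1:
        per_guide = rng.multinomial(n1, p_guide)
        harvest += rng.binomial(per_guide, survival**multipliers)
    # Multi-infected cells: vectorized within each multiplicity class.
    for ki, nk in enumerate(cells_by_k[1:], start=2):
        nk = int(nk)
        if nk == 0:
            continue
        idx = rng.choice(n_guides, size=(nk, ki), p=p_guide)
        combined = multipliers[idx].prod(axis=1)
        alive = rng.random(nk) < survival**combined
        if alive.any():
            harvest += np.bincount(idx[alive].ravel(), minlength=n_guides)

    total = harvest.sum()
    if total == 0:
        return harvest, np.zeros(n_guides, dtype=np.int64)
    freq = harvest / total
    if pcr_dispersion is not None:
        # Gamma jitter on guide frequencies models PCR amplification noise.
        w = rng.gamma(pcr_dispersion, 1.0 / pcr_dispersion, size=n_guides)
        freq = freq * w
        freq /= freq.sum()
    reads = rng.multinomial(depth, freq)
    return harvest, reads


def simulate_screen(
    lib: GuideLibrary,
    effects: GeneEffectProfile,
    moi_f: float = 0.25,
    n_cells: int = 100_000,
    harvest_t: float = 1.0,
    depth: int = 1_000_000,
    n_samples_per_arm: int = 3,
    seed: int = 0,
    degeneration: DegenerationModel | None = None,
    pcr_dispersion: float | None = None,
    survival_jitter_sd: float = 0.0,
) -> tuple[ScreenExperiment, ScreenExperiment]:
    """Simulate paired Cas9-positive and Cas9-negative screen arms.

    Each sample (retina) is an independent population of ``n_cells`` infected
    cells harvested at ``harvest_t`` months and sequenced to ``depth`` total
    reads.  Knockout effects act only in the Cas9-positive arm.  Returns the
    (Cas9+, Cas9-) pair; identical seeds give identical read matrices.

    ``survival_jitter_sd`` adds per-retina overdispersion: each sample's
    hazard is scaled by a lognormal factor exp(N(0, sd)), modeling animal-
    to-animal variation in degeneration severity (off by default).
    """
    if len(lib) == 0:
        raise ValueError("empty library")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    model = degeneration or DegenerationModel()
    s = survival_fraction(model, harvest_t)
    gene_of = np.array([g.target_gene for g in lib.guides])
    mult = np.array([effects.multiplier(g) for g in gene_of])
    neutral = np.ones_like(mult)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(2 * n_samples_per_arm)
    experiments = []
    for arm, arm_mult, offset in (
        ("cas9_pos", mult, 0),
        ("cas9_neg", neutral, n_samples_per_arm),
    ):
        cells = np.zeros((len(lib), n_samples_per_arm), dtype=np.int64)
        reads = np.zeros((len(lib), n_samples_per_arm), dtype=np.int64)
        names = []
        for j in range(n_samples_per_arm):
            rng = np.random.default_rng(child_seeds[offset + j])
            s_sample = s
            if survival_jitter_sd > 0:
                s_sample = s ** float(np.exp(rng.normal(0.0, survival_jitter_sd)))
            cells[:, j], reads[:, j] = _simulate_arm_sample(
                lib, arm_mult, moi_f, n_cells, s_sample, depth, rng, pcr_dispersion
            )
            names.append(f"{arm}_{j + 1}")
        experiments.append(
            ScreenExperiment(lib, arm, names, cells, reads, n_cells, seed)
        )
    return experiments[0], experiments[1]


# ---------------------------------------------------------------------------
# Amplicon reads


def emit_fastq(
    experiment: ScreenExperiment,
    out_dir: str | Path,
    seed: int = 0,
    read_length: int = 60,
    error_rate: float = 0.0,
    max_stagger: int = 7,
    gzip_output: bool = False,
) -> dict[str, Path]:
    """Write one FASTQ (optionally gzipped) per sample; {sample_name: path}.

    Read layout: [0-7 random stagger bases] + anchor + 20-nt protospacer +
    scaffold filler, truncated/padded to ``read_length``; constant Phred+33
    quality 'I'.  Record counts equal the read-count matrix column totals.
    """
    import gzip as _gzip
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    protos = np.array([g.protospacer for g in experiment.library.guides])
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(experiment.sample_names))
    paths: dict[str, Path] = {}
    for j, sample in enumerate(experiment.sample_names):
        rng = np.random.default_rng(child[j])
        counts = experiment.read_counts[:, j]
        n_reads = int(counts.sum())
        guide_idx = np.repeat(np.arange(len(protos)), counts)
        rng.shuffle(guide_idx)
        staggers = rng.integers(0, max_stagger + 1, size=n_reads)
        stagger_pool = _BASES[rng.integers(0, 4, size=(n_reads, max_stagger))]
        suffix = ".fastq.gz" if gzip_output else ".fastq"
        path = out_dir / f"{sample}{suffix}"
        opener = (lambda p: _gzip.open(p, "wt")) if gzip_output else (
            lambda p: open(p, "w", newline="\n")
        )
        qual = "I" * read_length
        with opener(path) as fh:
            for i in range(n_reads):
                st = int(staggers[i])
                prefix = "".join(stagger_pool[i, :st]) if st else ""
                seq = prefix + ANCHOR + protos[guide_idx[i]] + SCAFFOLD
                seq = seq[:read_length].ljust(read_length, "G")
                if error_rate > 0.0:
                    seq = _mutate(seq, error_rate, rng)
                fh.write(f"@{sample}.{i + 1}\n{seq}\n+\n{qual}\n")
        paths[sample] = path
    return paths


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        subs = _BASES[rng.integers(0, 4, size=hit.size)].astype("S1")
        arr[hit] = subs
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Phenotype generators


@dataclass(frozen=True)
class SyntheticERGConfig:
    """Flash ERG trace parameters (amplitudes in microvolts, times in s).

    b_amplitude is the peak-to-trough amplitude (filtered b-peak minus
    a-trough) and must be >= a_amplitude for a physiological trace.
    """

    sampling_rate: float = 2000.0
    duration: float = 0.5
    flash_onset: float = 0.05
    a_amplitude: float = 200.0
    a_latency: float = 0.020
    b_amplitude: float = 400.0
    b_center: float = 0.120
    b_halfwidth: float = 0.050
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.a_amplitude < 0 or self.b_amplitude < self.a_amplitude:
            raise ValueError("require 0 <= a_amplitude <= b_amplitude")


@dataclass(frozen=True)
class SyntheticPLRConfig:
    """PLR intensity-response parameters on the half-log stimulus grid."""

    ec50: float = 10**2.5
    hill_n: float = 1.0
    max_constriction: float = 0.9
    log10_min: float = 0.0
    log10_max: float = 5.0
    log10_step: float = 0.5
    noise_sd: float = 0.0

    def intensity_grid(self) -> np.ndarray:
        exps = np.arange(self.log10_min, self.log10_max + 1e-9, self.log10_step)
        return 10.0**exps

    def __post_init__(self) -> None:
        grid = self.intensity_grid()
        if not grid.min() <= self.ec50 <= grid.max():
            raise ValueError("EC50 must lie within the intensity grid")


@dataclass(frozen=True)
class SyntheticCliffConfig:
    """Visual-cliff trial parameters (ten trials per animal by default)."""

    p_shallow: float = 0.8
    n_trials: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_shallow <= 1.0:
            raise ValueError("p_shallow must be in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")


def simulate_erg_trace(cfg: SyntheticERGConfig, seed: int = 0) -> ERGTrace:
    """Synthetic flash ERG: negative a-wave dip plus slow positive b-wave.

    Constructed so that the stated feature definitions recover the configured
    amplitudes: the trace minimum within 50 ms of onset is -a_amplitude, and
    the post-flash maximum of the slow b-component is
    b_amplitude - a_amplitude above baseline (so peak-to-trough equals
    b_amplitude).
    """
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration * cfg.sampling_rate)) + 1
    t = np.arange(n) / cfg.sampling_rate
    rel = t - cfg.flash_onset
    v = np.zeros(n)
    post = rel > 0
    # a-wave: sharp negative deflection peaking at a_latency with value -A.
    x = rel[post] / cfg.a_latency
    v[post] -= cfg.a_amplitude * x**2 * np.exp(2.0 * (1.0 - x))
    # b-wave: raised-cosine bump (slow, passed by a 15-25 Hz low-pass).
    in_bump = np.abs(rel - cfg.b_center) <= cfg.b_halfwidth
    phase = (rel[in_bump] - cfg.b_center) / cfg.b_halfwidth
    v[in_bump] += (cfg.b_amplitude - cfg.a_amplitude) * np.cos(np.pi * phase / 2) ** 2
    if cfg.noise_sd > 0:
        v += rng.normal(0.0, cfg.noise_sd, size=n)
    return ERGTrace(t, v, cfg.flash_onset, cfg.sampling_rate)


def simulate_plr(cfg: SyntheticPLRConfig, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic PLR series: (intensities, relative pupil areas).

    relative area = 1 - max_constriction * I^n / (I^n + EC50^n) + noise.
    """
    rng = np.random.default_rng(seed)
    grid = cfg.intensity_grid()
    ratio = (grid / cfg.ec50) ** cfg.hill_n
    resp = 1.0 - cfg.max_constriction * ratio / (1.0 + ratio)
    if cfg.noise_sd > 0:
        resp = resp + rng.normal(0.0, cfg.noise_sd, size=grid.size)
    return grid, resp


def simulate_cliff(cfg: SyntheticCliffConfig, seed: int = 0) -> np.ndarray:
    """Boolean per-trial outcomes (True = shallow side chosen)."""
    rng = np.random.default_rng(seed)
    return rng.random(cfg.n_trials) < cfg.p_shallow
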