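"""Gene-level depletion/enrichment scoring (normZ) for dropout screens.

Implements the normZ scheme for comparing guide abundance between a
selection arm (Cas9-positive retinas, where knockouts act) and a control
arm (Cas9-negative retinas):

1. counts are scaled to a common total (1e7) and a pseudocount added;
2. per control-treatment pairing, guide fold changes log2(T/C) are
   standardized by an empirical-Bayes moderated standard deviation — the
   sliding-window sd of fold changes among guides of similar control
   abundance, enforced monotone non-decreasing toward lower abundance
   (low-count guides are noisier);
3. per gene, Z-scores are summed over guides and pairings and divided by
   sqrt(number of observations), then the resulting vector is re-centered
   and re-scaled to unit sd across genes (normZ);
4. one-sided normal p-values in each direction with Benjamini-Hochberg FDR,
   depletion ranks (1 = most depleted), and threshold-based candidate sets.

Negative normZ marks depletion (knockout accelerated cell loss, i.e. a
neuroprotective gene); positive normZ marks enrichment.  Non-targeting
controls are excluded from gene rows.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .library_model import NON_TARGETING

NORMALIZATION_TOTAL = 1.0e7


def normalize_counts(
    counts: pd.DataFrame,
    pseudocount: float = 0.5,
    total: float = NORMALIZATION_TOTAL,
) -> pd.DataFrame:
    """Scale each sample to a common total and add a pseudocount.

    Output is strictly positive and invariant to per-sample scaling of the
    raw counts.  A sample with zero total reads is an error.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    sums = counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    return counts / sums * total + pseudocount


def pair_samples(
    control_samples: Sequence[str], treatment_samples: Sequence[str]
) -> list[tuple[str, str]]:
    """Control-treatment pairings: sorted order, remainder paired round-robin."""
    ctrl = sorted(control_samples)
    trt = sorted(treatment_samples)
    if not ctrl or not trt:
        raise ValueError("need >= 1 control and >= 1 treatment sample")
    n = max(len(ctrl), len(trt))
    return [(ctrl[i % len(ctrl)], trt[i % len(trt)]) for i in range(n)]


def _moderated_sd(fc: np.ndarray, ctrl_abundance: np.ndarray, window: int) -> np.ndarray:
    """Empirical-Bayes sd per guide, indexed like the inputs.

    Guides are sorted by control abundance (descending); each guide's sd is
    the sd of fold changes in a window of ``window`` guides around it,
    enforced monotone non-decreasing toward lower abundance.  Guides tied on
    control abundance share the tie group's final sd, making the result
    independent of tie ordering.
    """
    n = fc.size
    w = int(min(window, max(n // 2, 2)))
    half = max(w // 2, 1)
    order = np.argsort(-ctrl_abundance, kind="stable")
    fc_sorted = fc[order]
    sd_sorted = np.empty(n)
    for i in range(n):
        start = min(max(i - half, 0), max(n - 2 * half, 0))
        end = min(start + 2 * half, n)
        sd_sorted[i] = fc_sorted[start:end].std(ddof=1)
    sd_sorted = np.maximum.accumulate(sd_sorted)
    # Uniform sd within control-abundance tie groups (take the group max).
    ab_sorted = ctrl_abundance[order]
    i = n - 1
    while i >= 0:
        j = i
        while j > 0 and ab_sorted[j - 1] == ab_sorted[i]:
            j -= 1
        sd_sorted[j : i + 1] = sd_sorted[i]
        i = j - 1
    out = np.empty(n)
    out[order] = sd_sorted
    return out


def guide_zscores(
    normalized: pd.DataFrame,
    control_samples: Sequence[str],
    treatment_samples: Sequence[str],
    eb_window: int = 800,
    nontargeting_guides: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-guide Z-scores, one column per control-treatment pairing.

    When ``nontargeting_guides`` is given, the empirical sd of those guides'
    fold changes becomes a floor on every moderated sd (the controls
    calibrate the null noise level).
    """
    if eb_window < 2:
        raise ValueError("eb_window must be >= 2")
    if len(normalized) < 2:
        raise ValueError("need >= 2 guides")
    nt_mask = None
    if nontargeting_guides is not None:
        nt_mask = normalized.index.isin(nontargeting_guides)
        if nt_mask.sum() < 2:
            raise ValueError("need >= 2 non-targeting guides for the sd floor")
    pairs = pair_samples(control_samples, treatment_samples)
    z = {}
    for k, (c, t) in enumerate(pairs):
        fc = np.log2(normalized[t].to_numpy() / normalized[c].to_numpy())
        sd = _moderated_sd(fc, normalized[c].to_numpy(), eb_window)
        if nt_mask is not None:
            sd = np.maximum(sd, fc[nt_mask].std(ddof=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            zk = np.where(sd > 0, fc / np.where(sd > 0, sd, 1.0), 0.0)
        z[f"z_{c}__{t}"] = zk
    return pd.DataFrame(z, index=normalized.index)


def gene_normz(
    guide_z: pd.DataFrame,
    guide_to_gene: Mapping[str, str],
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Aggregate guide Z-scores into a gene score table.

    Columns: normz, p_depletion, fdr_depletion, p_enrichment,
    fdr_enrichment, rank_depletion, n_guides.  Non-targeting guides are
    excluded.  A degenerate score vector (zero variance across genes) is
    reported as no evidence: normZ 0, p 1, FDR 1 for every gene.
    """
    genes = pd.Series({g: guide_to_gene[g] for g in guide_z.index})
    keep = genes != NON_TARGETING
    z = guide_z.loc[keep.index[keep]]
    if z.empty:
        raise ValueError("no targeting guides to score")

    flat = z.stack(future_stack=True).rename("z").reset_index()
    flat.columns = ["guide_id", "pairing", "z"]
    flat["gene"] = flat["guide_id"].map(guide_to_gene)
    flat = flat.dropna(subset=["z"])
    grouped = flat.groupby("gene")["z"]
    sumz = grouped.sum()
    nobs = grouped.count()
    n_guides = flat.groupby("gene")["guide_id"].nunique()
    raw = sumz / np.sqrt(nobs)

    spread = raw.std(ddof=0)
    if spread == 0 or np.isnan(spread):
        normz = pd.Series(0.0, index=raw.index)
        p_dep = pd.Series(1.0, index=raw.index)
        p_enr = pd.Series(1.0, index=raw.index)
        fdr_dep = p_dep.copy()
        fdr_enr = p_enr.copy()
    else:
        normz = (raw - raw.mean()) / spread
        p_dep = pd.Series(stats.norm.cdf(normz), index=normz.index)
        p_enr = pd.Series(stats.norm.sf(normz), index=normz.index)
        fdr_dep = pd.Series(
            multipletests(p_dep, method=fdr_method)[1], index=normz.index
        )
        fdr_enr = pd.Series(
            multipletests(p_enr, method=fdr_method)[1], index=normz.index
        )

    table = pd.DataFrame(
        {
            "normz": normz,
            "p_depletion": p_dep,
            "fdr_depletion": fdr_dep,
            "p_enrichment": p_enr,
            "fdr_enrichment": fdr_enr,
            "n_guides": n_guides,
        }
    )
    # Depletion rank: ascending normZ, ties broken by gene id (deterministic).
    ordered = sorted(table.index, key=lambda g: (table.at[g, "normz"], g))
    table["rank_depletion"] = pd.Series(
        np.arange(1, len(ordered) + 1), index=ordered
    )
    return table.sort_values("rank_depletion")


def select_candidates(
    table: pd.DataFrame, z_threshold: float = 2.0
) -> tuple[set[str], set[str]]:
    """(depleted, enriched) gene sets at |normZ| beyond the threshold."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    depleted = set(table.index[table["normz"] < -z_threshold])
    enriched = set(table.index[table["normz"] > z_threshold])
    return depleted, enriched


def select_secondary_targets(
    table: pd.DataFrame, top_n: int = 20, parity: str = "odd"
) -> list[str]:
    """Most-depleted ``top_n`` genes filtered to the requested rank parity.

    With (20, "odd") this returns the 10 genes at depletion ranks
    1, 3, ..., 19 — the secondary-screen selection rule.
    """
    if top_n > len(table):
        raise ValueError("top_n exceeds the number of scored genes")
    if parity not in {"odd", "even", "all"}:
        raise ValueError(f"parity must be odd|even|all, got {parity!r}")
    top = table.sort_values("rank_depletion").head(top_n)
    if parity == "odd":
        top = top[top["rank_depletion"] % 2 == 1]
    elif parity == "even":
        top = top[top["rank_depletion"] % 2 == 0]
    return list(top.index)


def score_screen(
    counts: pd.DataFrame,
    control_samples: Sequence[str],
    treatment_samples: Sequence[str],
    guide_to_gene: Mapping[str, str],
    pseudocount: float = 0.5,
    eb_window: int = 800,
) -> pd.DataFrame:
    """Full pipeline: raw counts -> gene score table."""
    normalized = normalize_counts(counts, pseudocount=pseudocount)
    z = guide_zscores(normalized, control_samples, treatment_samples, eb_window)
    return gene_normz(z, guide_to_gene)
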