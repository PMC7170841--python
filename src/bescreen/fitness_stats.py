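"""Abundance-change statistics and FDR-controlled fitness calls.

Per guide and replicate the fitness readout is the change in log2 relative
abundance between the mutagenesis time point (t0) and the end of the bulk
competition (t1):

    dlog2 = log2(n_guide_t1 / N_t1) - log2(n_guide_t0 / N_t0)

Each replicate's dlog2 distribution is standardised to z-scores, z-scores
are averaged across replicates, and a normal null is fitted to the averaged
z of the abundant synthesis-error (SE) guides — sequences that cannot edit
and therefore drift only by sampling noise.  The normal null converts any
z threshold into a false-positive rate, hence an expected false-positive
count among the tested guides, hence an FDR given the observed number of
hits; the reported threshold is the most permissive one meeting the target
FDR (default 10%).  Guides at or below it are GNEs (guides with negative
effect); the rest are NSGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screen_counts import CountTable, filter_min_reads, filter_presence

DEFAULT_FDR_TARGET = 0.10
DEFAULT_MIN_READS = 54
#: a zero count at t1 is replaced by this pseudocount before the ratio;
#: nonzero counts are never perturbed
ZERO_T1_PSEUDOCOUNT = 0.5


class FitnessError(ValueError):
    pass


@dataclass
class NullModel:
    mu_se: float
    sigma_se: float
    n_controls: int

    def __post_init__(self) -> None:
        if not self.sigma_se > 0:
            raise FitnessError("SE null sigma must be positive")

    def fpr(self, t: float) -> float:
        """Left-tail false-positive rate at z threshold t."""
        return float(stats.norm.cdf((t - self.mu_se) / self.sigma_se))


def delta_log2(count_t1, total_t1, count_t0, total_t0):
    """Change in log2 relative abundance between t0 and t1 (vectorised)."""
    count_t1 = np.asarray(count_t1, dtype=float)
    count_t0 = np.asarray(count_t0, dtype=float)
    if not (np.all(np.asarray(total_t1) > 0) and np.all(np.asarray(total_t0) > 0)):
        raise FitnessError("sample totals must be positive")
    if np.any(count_t0 <= 0):
        raise FitnessError("t0 counts must be positive for eligible guides")
    c1 = np.where(count_t1 == 0, ZERO_T1_PSEUDOCOUNT, count_t1)
    out = np.log2(c1 / total_t1) - np.log2(count_t0 / total_t0)
    return float(out) if out.ndim == 0 else out


def zscore_replicates(deltas: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Within-replicate z-scores (sample sd) and their cross-replicate mean.

    ``deltas`` is guides × replicates; standardisation uses every eligible
    guide in the column, SE controls included.
    """
    if len(deltas) < 3:
        raise FitnessError("need >= 3 guides per replicate to standardise")
    sd = deltas.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise FitnessError("degenerate dlog2 distribution (sd = 0)")
    z = (deltas - deltas.mean(axis=0)) / sd
    return z, z.mean(axis=1)


def fit_se_null(z_avg_se, min_controls: int = 10) -> NullModel:
    """Maximum-likelihood normal fit to abundant-SE averaged z-scores."""
    vals = np.asarray(z_avg_se, dtype=float)
    if len(vals) < min_controls:
        raise FitnessError(
            f"only {len(vals)} SE controls; need >= {min_controls}"
        )
    mu, sigma = float(np.mean(vals)), float(np.std(vals))  # ddof=0 (MLE)
    if sigma == 0:
        raise FitnessError("SE control z-scores are all identical")
    return NullModel(mu_se=mu, sigma_se=sigma, n_controls=len(vals))


def fdr_at_threshold(
    t: float, null: NullModel, z_tested
) -> tuple[float, float, int, float]:
    """(fpr, expected false positives, hits, FDR) at z threshold ``t``.

    ``z_tested`` holds the averaged z of the non-SE eligible guides — the
    population in which discoveries are made.
    """
    z = np.asarray(z_tested, dtype=float)
    fpr = null.fpr(t)
    expected_fp = fpr * len(z)
    n_hits = int(np.sum(z <= t))
    fdr = expected_fp / n_hits if n_hits > 0 else float("inf")
    return fpr, expected_fp, n_hits, fdr


def call_gnes(
    z_avg: pd.Series,
    is_se: pd.Series,
    null: NullModel,
    fdr_target: float = DEFAULT_FDR_TARGET,
) -> tuple[pd.DataFrame, float]:
    """GNE/NSG calls at the most permissive threshold meeting the FDR target.

    The threshold search walks the observed z values of tested (non-SE)
    guides only.  SE controls are never called GNE.  Returns (calls frame,
    threshold); threshold is -inf (zero GNEs) when no value meets the
    target.
    """
    is_se = is_se.reindex(z_avg.index).fillna(False).astype(bool)
    z_tested = np.sort(z_avg[~is_se].to_numpy(dtype=float))
    n = len(z_tested)
    if n == 0:
        raise FitnessError("no tested guides")
    fpr = stats.norm.cdf((z_tested - null.mu_se) / null.sigma_se)
    # hits at threshold z_tested[i] (ascending, ties share the last index)
    n_hits = np.searchsorted(z_tested, z_tested, side="right")
    fdr = fpr * n / n_hits
    ok = fdr <= fdr_target
    threshold = float(z_tested[ok][-1]) if ok.any() else float("-inf")
    call = np.where((z_avg <= threshold) & ~is_se, "GNE", "NSG")
    calls = pd.DataFrame(
        {
            "z_avg": z_avg,
            "is_se_control": is_se,
            "call": call,
            "z_threshold_used": threshold,
            "fdr_target": fdr_target,
        },
        index=z_avg.index,
    )
    return calls, threshold


def analyze_screen(
    table: CountTable,
    is_se: pd.Series,
    t0: str = "T0_mutagenesis",
    t1: str = "T_end",
    min_reads: int = DEFAULT_MIN_READS,
    fdr_target: float = DEFAULT_FDR_TARGET,
    apply_presence_filter: bool = True,
    min_se_controls: int = 10,
) -> dict:
    """Counts → dlog2 → z → SE null → GNE calls, end to end.

    Sample totals are the post-presence-filter column sums (the sequencing
    totals of the analysed library).  Eligibility requires the minimal t0
    read count in every replicate.  Returns a dict with the per-guide
    results frame, the fitted null, and the z threshold.
    """
    if apply_presence_filter:
        table = filter_presence(table)
    eligible = filter_min_reads(table, timepoint=t0, threshold=min_reads)
    totals = table.totals
    reps = table.replicates()
    deltas = {}
    for rep in reps:
        rep_samples = table.samples[table.samples["replicate"] == rep]
        c0 = rep_samples.index[rep_samples["timepoint"] == t0]
        c1 = rep_samples.index[rep_samples["timepoint"] == t1]
        if len(c0) != 1 or len(c1) != 1:
            raise FitnessError(f"replicate {rep}: need exactly one {t0} and one {t1}")
        s0, s1 = c0[0], c1[0]
        deltas[rep] = pd.Series(
            delta_log2(
                table.counts.loc[eligible, s1], totals[s1],
                table.counts.loc[eligible, s0], totals[s0],
            ),
            index=eligible,
        )
    deltas = pd.DataFrame(deltas)
    z, z_avg = zscore_replicates(deltas)
    is_se = is_se.reindex(eligible).fillna(False).astype(bool)
    null = fit_se_null(z_avg[is_se], min_controls=min_se_controls)
    calls, threshold = call_gnes(z_avg, is_se, null, fdr_target)
    results = pd.concat(
        [
            deltas.rename(columns={r: f"delta_log2_{r}" for r in reps}),
            z.rename(columns={r: f"z_{r}" for r in reps}),
            calls,
        ],
        axis=1,
    )
    results.index.name = "guide_id"
    return {
        "results": results,
        "null": null,
        "threshold": threshold,
        "n_eligible": len(eligible),
        "n_tested": int((~is_se).sum()),
        "n_gne": int((results["call"] == "GNE").sum()),
    }
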