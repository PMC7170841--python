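"""GNE-vs-NSG comparisons: substitution patterns, annotations, features.

All tests are two-sided Fisher's exact tests on 2×2 tables; families of
pattern tests are corrected with the Holm step-down procedure (FWER at
alpha; a Benjamini–Hochberg option is provided for users who prefer FDR
control).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """Rows {GNE, NSG} × columns {has property, lacks property}."""

    a: int  # GNE with property
    b: int  # GNE without
    c: int  # NSG with property
    d: int  # NSG without

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EnrichmentError("negative contingency entry")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_2x2(table) -> tuple[float, float]:
    """Exact two-sided Fisher test; returns (odds ratio, p)."""
    if isinstance(table, ContingencyTable):
        arr = table.as_array()
    else:
        arr = np.asarray(table)
    if arr.min() < 0:
        raise EnrichmentError("negative contingency entry")
    a, b = arr[0]
    c, d = arr[1]
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return odds, float(p)


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Holm step-down rejections at family-wise error level ``alpha``."""
    p = list(p_values)
    if not p:
        return []
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return [bool(r) for r in reject]


def benjamini_hochberg(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    p = list(p_values)
    if not p:
        return []
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return [bool(r) for r in reject]


def pattern_key(outcomes, target_class: str = "essential") -> str:
    """Mutation-pair label for a guide from its rank-1 model-set outcomes.

    The two rank-1 genotypes (C→G then C→T) give e.g. ``G→R/S``; a stop is
    '*'; a silent outcome repeats the reference residue.  Intron and
    putative-peptide guides form their own classes.
    """
    if target_class in ("intron", "putative_peptide"):
        return target_class
    top = [g for g in outcomes if g.edits[0][0] == outcomes[0].edits[0][0]]
    by_alt = {g.edits[0][2]: g for g in top}
    labels = {}
    ref_aa = None
    for alt in ("G", "T"):
        g = by_alt.get(alt)
        if g is None:
            continue
        if g.target_residue is not None:
            ref_aa = g.target_residue[1]
        # a silent outcome repeats the reference residue
        labels[alt] = g.aa_changes[0][2] if g.aa_changes else ref_aa
    g_lab = labels.get("G", "?")
    t_lab = labels.get("T", "?")
    return f"{ref_aa}→{g_lab}/{t_lab}"


def pattern_enrichment(
    gne_keys: Sequence[str],
    nsg_keys: Sequence[str],
    alpha: float = 0.05,
    method: str = "holm",
) -> pd.DataFrame:
    """Per-pattern fold enrichment of GNEs over NSGs with exact tests.

    fold = (pattern share among GNEs) / (share among NSGs); each pattern's
    2×2 table is pattern-vs-not × GNE-vs-NSG.
    """
    if not gne_keys or not nsg_keys:
        raise EnrichmentError("both guide sets must be non-empty")
    gne = pd.Series(gne_keys).value_counts()
    nsg = pd.Series(nsg_keys).value_counts()
    n_gne, n_nsg = len(gne_keys), len(nsg_keys)
    rows = []
    for key in sorted(set(gne.index) | set(nsg.index)):
        a = int(gne.get(key, 0))
        c = int(nsg.get(key, 0))
        odds, p = fisher_2x2(ContingencyTable(a, n_gne - a, c, n_nsg - c))
        fold = (a / n_gne) / (c / n_nsg) if c > 0 else float("inf")
        rows.append({"pattern": key, "gne": a, "nsg": c, "fold": fold,
                     "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows).set_index("pattern")
    adjust = holm_bonferroni if method == "holm" else benjamini_hochberg
    df["rejected"] = adjust(df["p"].tolist(), alpha=alpha)
    return df


def annotation_enrichment(
    guides: pd.DataFrame,
    annotations: pd.DataFrame,
    window_aa: int = 2,
) -> dict:
    """On-site and near-site enrichment of GNEs at annotated residues.

    ``guides`` needs columns gene_id, residue (1-based target residue) and
    is_gne; ``annotations`` needs gene_id and residue.  A guide is on-site
    when its residue is annotated in its gene, near-site when within
    ``window_aa`` residues (but not on-site).  Each status is tested
    against all remaining guides (status vs not × GNE vs NSG).
    Annotations for genes absent from ``guides`` are skipped.
    """
    known = set(guides["gene_id"])
    ann = annotations[annotations["gene_id"].isin(known)]
    sites: dict[str, set[int]] = {}
    for g, r in zip(ann["gene_id"], ann["residue"]):
        sites.setdefault(g, set()).add(int(r))
    status = []
    for g, r in zip(guides["gene_id"], guides["residue"]):
        s = sites.get(g, set())
        r = int(r)
        if r in s:
            status.append("on")
        elif s and window_aa > 0 and any(abs(r - x) <= window_aa for x in s):
            status.append("near")
        else:
            status.append("off")
    status = pd.Series(status, index=guides.index)
    is_gne = guides["is_gne"].astype(bool)
    out = {"n_skipped_annotations": int(len(annotations) - len(ann))}
    for label in ("on", "near"):
        mask = status == label
        tab = ContingencyTable(
            int((mask & is_gne).sum()), int((~mask & is_gne).sum()),
            int((mask & ~is_gne).sum()), int((~mask & ~is_gne).sum()),
        )
        odds, p = fisher_2x2(tab)
        out[label] = {
            "table": tab,
            "odds_ratio": odds,
            "p": p,
            "ratio_gne": tab.a / (tab.a + tab.b) if tab.a + tab.b else float("nan"),
            "ratio_nsg": tab.c / (tab.c + tab.d) if tab.c + tab.d else float("nan"),
        }
    return out


def feature_comparison(gne_values, nsg_values) -> dict:
    """Welch's unequal-variance t-test between GNE and NSG feature values."""
    x = np.asarray(gne_values, dtype=float)
    y = np.asarray(nsg_values, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise EnrichmentError("need >= 2 values per group")
    if np.var(x) == 0 and np.var(y) == 0:
        raise EnrichmentError("degenerate variance in both groups")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return {
        "welch_t": float(t),
        "p": float(p),
        "mean_gne": float(np.mean(x)),
        "mean_nsg": float(np.mean(y)),
        "median_gne": float(np.median(x)),
        "median_nsg": float(np.median(y)),
    }


def gne_ratio_by_bin(
    values, is_gne, bin_edges
) -> pd.DataFrame:
    """Per-bin GNE enrichment relative to the overall GNE ratio."""
    values = np.asarray(values, dtype=float)
    is_gne = np.asarray(is_gne, dtype=bool)
    edges = np.asarray(bin_edges, dtype=float)
    if values.min() < edges[0] or values.max() > edges[-1]:
        raise EnrichmentError("bins do not cover the feature range")
    overall = is_gne.mean()
    idx = np.clip(np.digitize(values, edges, right=False) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        n_gne = int((mask & is_gne).sum())
        ratio = n_gne / n if n else float("nan")
        rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1], "n": n,
            "n_gne": n_gne, "gne_ratio": ratio,
            "enrichment": ratio / overall if n and overall > 0 else float("nan"),
        })
    return pd.DataFrame(rows)


def spearman(x, y) -> tuple[float, float]:
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
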