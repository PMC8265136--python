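"""Two-group differential abundance testing with FDR control.

The workhorse is the two-sided Wilcoxon rank-sum (Mann-Whitney) test applied
feature by feature, with Benjamini-Hochberg correction within each taxonomic
rank. Exact p-values are used for small tie-free samples; otherwise the
normal approximation with tie-corrected variance and continuity correction
is applied, mirroring R's ``wilcox.test`` defaults. Enrichment direction is
assigned to the group with the higher median relative abundance (mean as
tie-break), a robust choice for sparse compositional data.

Subgroup contrasts split cases on the acetylcholine-receptor antibody
(AChRAb) titre at the clinical positivity threshold of 0.5 nmol/L
(seropositive strictly above).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError
from .profile_io import AbundanceTable, SampleMetadata

#: default FDR threshold for calling a feature significantly different
DEFAULT_Q_THRESHOLD = 0.05
#: AChRAb seropositivity cutoff, nmol/L (positive strictly above)
ACHRAB_POSITIVE_CUTOFF = 0.5
#: largest combined sample size for which tie-free exact p-values are computed
EXACT_CUTOFF = 20


def wilcoxon_rank_sum(
    x,
    y,
    alternative: str = "two-sided",
    exact_cutoff: int = EXACT_CUTOFF,
) -> tuple[float, float]:
    """Wilcoxon rank-sum test of two independent samples.

    Returns ``(U, p)`` where ``U`` is the Mann-Whitney statistic of ``x``
    (R's ``W``). The p-value is exact (distribution enumeration) when the
    pooled data has no ties and combined n <= ``exact_cutoff``; otherwise the
    normal approximation with tie-corrected variance and a continuity
    correction toward the mean is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    u = w - n1 * (n1 + 1) / 2.0

    _, counts = np.unique(pooled, return_counts=True)
    has_ties = (counts > 1).any()
    if not has_ties and n1 + n2 <= exact_cutoff:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
        return float(res.statistic), float(res.pvalue)

    mu = n1 * n2 / 2.0
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:  # all pooled values identical
        return float(u), 1.0
    z = u - mu
    sigma = np.sqrt(sigma2)
    if alternative == "two-sided":
        z = (z - np.sign(z) * 0.5) / sigma
        p = 2.0 * min(stats.norm.cdf(z), stats.norm.sf(z))
    elif alternative == "greater":
        p = stats.norm.sf((z - 0.5) / sigma)
    else:
        p = stats.norm.cdf((z + 0.5) / sigma)
    return float(u), float(min(p, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison rule over the sample metadata.

    ``achrab_status`` restricts the case group: ``"positive"`` keeps cases
    with AChRAb > ``achrab_cutoff`` nmol/L, ``"negative"`` keeps the rest,
    ``None`` keeps all cases. Controls are always the control group.
    """

    name: str = "case-vs-control"
    q_threshold: float = DEFAULT_Q_THRESHOLD
    achrab_status: str | None = None
    achrab_cutoff: float = ACHRAB_POSITIVE_CUTOFF

    @classmethod
    def case_vs_control(cls, q_threshold: float = DEFAULT_Q_THRESHOLD) -> "ContrastSpec":
        return cls("case-vs-control", q_threshold)

    @classmethod
    def achrab_positive_vs_control(
        cls, q_threshold: float = DEFAULT_Q_THRESHOLD
    ) -> "ContrastSpec":
        return cls("achrab-pos-vs-control", q_threshold, achrab_status="positive")

    @classmethod
    def achrab_negative_vs_control(
        cls, q_threshold: float = DEFAULT_Q_THRESHOLD
    ) -> "ContrastSpec":
        return cls("achrab-neg-vs-control", q_threshold, achrab_status="negative")

    def select_groups(self, metadata: SampleMetadata) -> tuple[list[str], list[str]]:
        """Return (case-like, control) sample id lists for this contrast."""
        cases = metadata.case_ids()
        controls = metadata.control_ids()
        if self.achrab_status is not None:
            if "achrab" not in metadata.data.columns:
                raise DataError("metadata lacks 'achrab' column for AChRAb contrast")
            ach = pd.to_numeric(metadata.data["achrab"], errors="coerce")
            positive = set(ach.index[ach > self.achrab_cutoff])
            if self.achrab_status == "positive":
                cases = [s for s in cases if s in positive]
            elif self.achrab_status == "negative":
                cases = [s for s in cases if s not in positive]
            else:
                raise ValueError(f"unknown achrab_status {self.achrab_status!r}")
        if not cases or not controls:
            raise DataError(f"contrast {self.name!r} has an empty group")
        return cases, controls


def differential_features(
    table: AbundanceTable,
    metadata: SampleMetadata,
    contrast: ContrastSpec | None = None,
    per_rank: bool = True,
    min_prevalence: int = 0,
) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum tests between the contrast's two groups.

    BH correction is applied within each taxonomic rank when ``per_rank``
    (ranks form separate test families), otherwise across all features.
    Returns a DataFrame with one row per tested feature: statistic, raw p,
    q, enrichment direction, per-group medians/means and prevalences, and a
    boolean ``significant`` column at the contrast's q threshold.
    """
    contrast = contrast or ContrastSpec.case_vs_control()
    cases, controls = contrast.select_groups(metadata)
    cases = [s for s in cases if s in table.data.columns]
    controls = [s for s in controls if s in table.data.columns]
    if not cases or not controls:
        raise DataError("contrast group empty after intersecting with abundance table")

    xs = table.data[cases].to_numpy()
    ys = table.data[controls].to_numpy()
    ranks = table.feature_ranks()

    rows = []
    for i, feature in enumerate(table.features):
        x, y = xs[i], ys[i]
        prev_case = int((x > 0).sum())
        prev_control = int((y > 0).sum())
        if prev_case + prev_control < min_prevalence:
            continue
        stat, p = wilcoxon_rank_sum(x, y)
        med_c, med_h = float(np.median(x)), float(np.median(y))
        mean_c, mean_h = float(x.mean()), float(y.mean())
        if med_c > med_h:
            enriched = "case"
        elif med_c < med_h:
            enriched = "control"
        elif mean_c > mean_h:
            enriched = "case"
        elif mean_c < mean_h:
            enriched = "control"
        else:
            enriched = "none"
        rows.append(
            {
                "feature": feature,
                "rank": ranks.iloc[i],
                "statistic": stat,
                "p": p,
                "enriched": enriched,
                "median_case": med_c,
                "median_control": med_h,
                "mean_case": mean_c,
                "mean_control": mean_h,
                "prevalence_case": prev_case / len(cases),
                "prevalence_control": prev_control / len(controls),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "feature",
            "rank",
            "statistic",
            "p",
            "enriched",
            "median_case",
            "median_control",
            "mean_case",
            "mean_control",
            "prevalence_case",
            "prevalence_control",
        ],
    )
    if result.empty:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    q = np.empty(len(result))
    if per_rank:
        for _, idx in result.groupby("rank").groups.items():
            q[result.index.get_indexer(idx)] = bh_adjust(result.loc[idx, "p"])
    else:
        q = bh_adjust(result["p"])
    result["q"] = q
    result["significant"] = result["q"] < contrast.q_threshold
    # a feature can only be called for a group, never "none"
    result.loc[result["enriched"] == "none", "significant"] = False
    cols = [
        "feature",
        "rank",
        "statistic",
        "p",
        "q",
        "enriched",
        "median_case",
        "median_control",
        "mean_case",
        "mean_control",
        "prevalence_case",
        "prevalence_control",
        "significant",
    ]
    return result[cols]


def spearman_phenotype_correlation(
    features: AbundanceTable,
    phenotypes: pd.DataFrame,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlation of each feature against each numeric phenotype.

    Missing values are handled pairwise-complete; pairs with fewer than
    ``min_pairs`` complete observations are reported as NaN rather than
    raising. BH adjustment is applied across the full feature x phenotype
    matrix. Returns (rho, p, q) DataFrames.
    """
    common = [s for s in features.samples if s in phenotypes.index]
    x = features.data[common]
    ph = phenotypes.loc[common].apply(pd.to_numeric, errors="coerce")
    rho = pd.DataFrame(np.nan, index=x.index, columns=ph.columns)
    pmat = pd.DataFrame(np.nan, index=x.index, columns=ph.columns)
    for col in ph.columns:
        pv = ph[col].to_numpy()
        for feat in x.index:
            fv = x.loc[feat].to_numpy(dtype=float)
            mask = ~(np.isnan(fv) | np.isnan(pv))
            if mask.sum() < min_pairs:
                continue
            a, b = fv[mask], pv[mask]
            if np.all(a == a[0]) or np.all(b == b[0]):
                continue  # zero variance: correlation undefined
            r, p = stats.spearmanr(a, b)
            rho.loc[feat, col] = r
            pmat.loc[feat, col] = p
    qmat = pmat.copy()
    flat = pmat.to_numpy().ravel()
    ok = ~np.isnan(flat)
    if ok.any():
        adj = np.full(flat.shape, np.nan)
        adj[ok] = bh_adjust(flat[ok])
        qmat.iloc[:, :] = adj.reshape(pmat.shape)
    return rho, pmat, qmat
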