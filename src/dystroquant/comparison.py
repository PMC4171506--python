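"""Assay precision and pre/post-treatment comparison statistics.

Precision is expressed as the percent coefficient of variation,
CV% = SD / mean × 100, computed with the sample (n−1) standard
deviation: intra-assay over replicate sections within one experiment,
inter-assay over the per-experiment means of the same biopsy.  Table
outputs round to integer percent (half away from zero); machine-readable
results keep full precision.

Pre/post comparisons within one experiment use the signed percent
difference, (post − pre) / pre × 100, and a hierarchical significance
test on log-transformed per-image means with visit as the fixed term and
sections-within-visit as random; images-within-section form the residual
stratum since each image contributes one mean value.  A section-level
permutation test is provided as a distribution-free alternative.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .population import BiopsySummary, CumulativeCurve, cumulative_distribution, is_right_shifted


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (table convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclasses.dataclass
class StudyDesign:
    """Per-image mean intensities nested as visit -> section -> image.

    ``table`` columns: ``visit`` (label, e.g. "pre"/"post"), ``section_id``,
    ``image_id``, ``value`` (au; per-image mean of per-fiber means).
    Section ids must be unique across visits (each section belongs to
    exactly one visit).
    """

    table: pd.DataFrame
    biopsy_label: str = ""
    experiment_label: str = ""
    operator_label: str = ""

    def __post_init__(self) -> None:
        required = {"visit", "section_id", "image_id", "value"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"StudyDesign table missing columns: {sorted(missing)}")
        visits_per_section = self.table.groupby("section_id")["visit"].nunique()
        if (visits_per_section > 1).any():
            bad = visits_per_section[visits_per_section > 1].index.tolist()
            raise ValueError(f"sections assigned to multiple visits: {bad}")

    @property
    def visits(self) -> list[str]:
        """Visit labels in contrast order (second minus first).

        The conventional "pre"/"post" pair is ordered pre first so the
        contrast reads post − pre; any other labels sort lexicographically.
        """
        labels = sorted(self.table["visit"].unique().tolist())
        if set(labels) == {"pre", "post"}:
            return ["pre", "post"]
        return labels

    def n_sections(self, visit: str | None = None) -> int:
        t = self.table if visit is None else self.table[self.table["visit"] == visit]
        return t["section_id"].nunique()

    def section_means(self, log: bool = False) -> pd.DataFrame:
        t = self.table.copy()
        t["y"] = np.log(t["value"]) if log else t["value"]
        return (
            t.groupby(["visit", "section_id"], sort=True)["y"]
            .mean()
            .reset_index()
        )


@dataclasses.dataclass
class PrecisionResult:
    cv_percent: float
    cv_percent_rounded: int
    mean: float
    sd: float
    n: int
    kind: str


def cv_percent(values: Sequence[float], kind: str = "inter") -> PrecisionResult:
    """Percent coefficient of variation of replicate mean intensities.

    Uses the sample standard deviation (n−1 denominator) over the
    arithmetic mean; ``kind`` labels the replicate level ("intra" for
    sections within one experiment, "inter" for experiment means).
    """
    arr = np.asarray(values, dtype=np.float64)
    if len(arr) < 2:
        raise ValueError("CV% needs at least two replicate values")
    mean = float(arr.mean())
    if mean <= 0:
        raise ValueError("CV% undefined for nonpositive mean intensity")
    sd = float(arr.std(ddof=1))
    cv = sd / mean * 100.0
    return PrecisionResult(
        cv_percent=cv,
        cv_percent_rounded=round_half_away(cv),
        mean=mean,
        sd=sd,
        n=len(arr),
        kind=kind,
    )


def rank_samples(
    means: Mapping[str, Mapping[str, float]] | pd.DataFrame,
) -> tuple[pd.DataFrame, bool]:
    """Rank samples by mean intensity within each experiment.

    ``means`` maps experiment label -> {sample label: mean au} (or an
    equivalent DataFrame with columns experiment/sample/mean).  Rank 1 is
    the highest intensity; ties are broken by sample label so the result
    is deterministic, and tied pairs are flagged in the ``tied`` column.
    Returns the rank table and a concordance flag that is True when all
    experiments produce the identical sample order.
    """
    if isinstance(means, pd.DataFrame):
        frame = means.copy()
    else:
        rows = [
            {"experiment": exp, "sample": sample, "mean": value}
            for exp, per_sample in means.items()
            for sample, value in per_sample.items()
        ]
        frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("no sample means to rank")

    out = []
    orders: list[tuple[str, ...]] = []
    for exp, group in frame.groupby("experiment", sort=True):
        group = group.sort_values(
            ["mean", "sample"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        dup = group["mean"].duplicated(keep=False)
        for i, row in group.iterrows():
            out.append(
                {
                    "experiment": exp,
                    "sample": row["sample"],
                    "mean": row["mean"],
                    "rank": i + 1,
                    "tied": bool(dup[i]),
                }
            )
        orders.append(tuple(group["sample"]))
    concordant = len(set(orders)) == 1
    return pd.DataFrame(out), concordant


def percent_difference(pre: float, post: float) -> float:
    """Signed percent change post vs pre: (post − pre) / pre × 100."""
    if pre <= 0:
        raise ValueError("pre-treatment intensity must be > 0")
    return (post - pre) / pre * 100.0


@dataclasses.dataclass
class VisitTestResult:
    """Hierarchical test of the visit (pre/post) effect on the log scale."""

    effect_log: float          # log(post) − log(pre) contrast
    se: float
    df: float
    p_value: float
    ratio: float               # exp(effect_log): multiplicative change
    var_section: float         # between-section variance component (log scale)
    var_image: float           # residual (image-within-section) variance
    n_sections: int
    n_images: int
    method: str = "reml-nested-anova"


def _check_design(design: StudyDesign) -> pd.DataFrame:
    t = design.table
    if (t["value"] <= 0).any():
        raise ValueError("all per-image mean values must be > 0 for the log transform")
    visits = design.visits
    if len(visits) != 2:
        raise ValueError(f"exactly two visits required, got {visits}")
    for v in visits:
        if design.n_sections(v) < 2:
            raise ValueError(
                f"visit '{v}' has a single section: the between-section stratum is "
                "empty; use permutation_visit_test(..., level='image') instead "
                "(note: image-level exchange is anti-conservative for this design)"
            )
        images_per_section = (
            t[t["visit"] == v].groupby("section_id")["image_id"].nunique()
        )
        if (images_per_section < 2).any():
            raise ValueError(f"every section needs >= 2 images (visit '{v}')")
    return t


def hierarchical_visit_test(design: StudyDesign) -> VisitTestResult:
    """Mixed-effects test of the visit effect on log per-image means.

    Model: log(y) = mu + visit + section(visit) + image residual, with
    sections as random intercepts.  Variance components come from a REML
    fit; inference on the visit contrast uses the between-section stratum
    (the classical nested-ANOVA t on per-section means, df = S − 2),
    which is exact under normality for balanced designs and does not rely
    on a large-sample z approximation.  Visits are ordered
    lexicographically; the contrast is second minus first (with the
    conventional "post"/"pre" labels this is post − pre).
    """
    t = _check_design(design)
    visits = design.visits
    y = np.log(t["value"].to_numpy())
    sec = design.section_means(log=True)
    g0 = sec.loc[sec["visit"] == visits[0], "y"].to_numpy()
    g1 = sec.loc[sec["visit"] == visits[1], "y"].to_numpy()
    effect = float(g1.mean() - g0.mean())

    n_sections = len(g0) + len(g1)
    n_images = len(t)

    # within-visit pooled variance of section means -> SE of the contrast
    ss = float(((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum())
    df = n_sections - 2
    pooled = ss / df if df > 0 else 0.0
    se = math.sqrt(pooled * (1.0 / len(g0) + 1.0 / len(g1)))

    var_section, var_image = _reml_variance_components(t, visits)

    if se == 0.0:
        # no-noise limit: section means identical within visits
        p = 0.0 if effect != 0 else 1.0
    else:
        from scipy import stats

        p = float(2.0 * stats.t.sf(abs(effect) / se, df))

    return VisitTestResult(
        effect_log=effect,
        se=se,
        df=float(df),
        p_value=p,
        ratio=float(math.exp(effect)),
        var_section=var_section,
        var_image=var_image,
        n_sections=n_sections,
        n_images=n_images,
    )


def _reml_variance_components(t: pd.DataFrame, visits: list[str]) -> tuple[float, float]:
    """REML variance components (section, image) for the nested design."""
    y = np.log(t["value"].to_numpy())
    if np.ptp(y) < 1e-12:
        return 0.0, 0.0
    exog = np.column_stack(
        [np.ones(len(t)), (t["visit"] == visits[1]).to_numpy(float)]
    )
    try:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=t["section_id"].to_numpy())
            fit = model.fit(reml=True, method="lbfgs")
        return float(np.asarray(fit.cov_re)[0, 0]), float(fit.scale)
    except Exception:
        # method-of-moments fallback on the nested ANOVA strata
        resid = y - np.array(
            [t.groupby("section_id")["value"].transform(lambda v: np.log(v).mean())]
        ).ravel()
        var_image = float(np.var(resid, ddof=t["section_id"].nunique()))
        return 0.0, var_image


def permutation_visit_test(
    design: StudyDesign,
    n_permutations: int = 10000,
    seed: int | None = None,
    level: str = "section",
    max_exact: int = 20000,
) -> tuple[float, float]:
    """Distribution-free visit test permuting labels at the section level.

    The statistic is the difference of visit means of per-section log
    means.  All section-to-visit reassignments are enumerated when their
    count is at most ``max_exact`` (exact randomization p-value);
    otherwise Monte Carlo with ``n_permutations`` draws and the add-one
    estimator.  ``level='image'`` exchanges image values instead — only
    for degenerate single-section designs, and anti-conservative because
    images within a section are correlated.
    Returns (observed statistic, p-value).
    """
    t = design.table
    visits = design.visits
    if level == "section":
        sec = design.section_means(log=True)
        values = sec["y"].to_numpy()
        labels = (sec["visit"] == visits[1]).to_numpy()
    elif level == "image":
        values = np.log(t["value"].to_numpy())
        labels = (t["visit"] == visits[1]).to_numpy()
    else:
        raise ValueError("level must be 'section' or 'image'")

    n = len(values)
    n1 = int(labels.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both visits need at least one unit at the chosen level")

    def stat(mask: np.ndarray) -> float:
        return float(values[mask].mean() - values[~mask].mean())

    observed = stat(labels)
    n_combos = math.comb(n, n1)
    if n_combos <= max_exact:
        count = 0
        for combo in itertools.combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            if abs(stat(mask)) >= abs(observed) - 1e-12:
                count += 1
        p = count / n_combos
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n1, replace=False)] = True
            if abs(stat(mask)) >= abs(observed) - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    return observed, p


@dataclasses.dataclass
class ComparisonReport:
    """Bundled pre/post comparison of one biopsy pair."""

    percent_difference: float
    percent_difference_rounded: int
    right_shifted: bool | None
    visit_test: VisitTestResult
    permutation_p: float | None
    pre_mean: float
    post_mean: float
    warnings: list[str]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["visit_test"] = dataclasses.asdict(self.visit_test)
        return d


def compare_visits(
    pre_summary: BiopsySummary,
    post_summary: BiopsySummary,
    design: StudyDesign,
    pre_fiber_values: Sequence[float] | None = None,
    post_fiber_values: Sequence[float] | None = None,
    run_permutation: bool = True,
    seed: int | None = 0,
) -> ComparisonReport:
    """Pre/post comparison: % difference, S-curve shift, hierarchical test.

    The percent difference is computed on the biopsy averages of
    per-fiber mean intensities; the S-curve shift assessment needs the
    per-fiber values of both arms and is skipped (None) when they are not
    supplied.  Mismatched staining combinations are recorded as a
    warning in the report, not an error.
    """
    notes: list[str] = []
    if (
        pre_summary.staining_combo
        and post_summary.staining_combo
        and pre_summary.staining_combo != post_summary.staining_combo
    ):
        notes.append(
            "staining_combo mismatch: "
            f"pre='{pre_summary.staining_combo}' post='{post_summary.staining_combo}'"
        )
    diff = percent_difference(pre_summary.avg_dys_mean, post_summary.avg_dys_mean)
    shifted: bool | None = None
    if pre_fiber_values is not None and post_fiber_values is not None:
        shifted = is_right_shifted(
            cumulative_distribution(pre_fiber_values),
            cumulative_distribution(post_fiber_values),
        )
    test = hierarchical_visit_test(design)
    perm_p = None
    if run_permutation:
        _, perm_p = permutation_visit_test(design, seed=seed)
    return ComparisonReport(
        percent_difference=diff,
        percent_difference_rounded=round_half_away(diff),
        right_shifted=shifted,
        visit_test=test,
        permutation_p=perm_p,
        pre_mean=pre_summary.avg_dys_mean,
        post_mean=post_summary.avg_dys_mean,
        warnings=notes,
    )
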