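"""Survey and patient-characteristic comparisons.

Likert items are dichotomized (e.g. agree/strongly agree vs the rest)
into phase × endorsement fourfold tables compared with the uncorrected
Pearson chi-square; ordinal and numeric items (years of experience,
minutes per shift, age, Glasgow Coma Scale) use the two-sided
Wilcoxon-Mann-Whitney rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .core import Phase, round_half_away


@dataclass(frozen=True)
class LikertResponse:
    item_id: str
    level: int
    phase: Phase


@dataclass
class FourfoldTable:
    """2×2 phase × endorsement table: rows (pre, post), cols (endorsed, not)."""

    a: int  # pre, endorsed
    b: int  # pre, not endorsed
    c: int  # post, endorsed
    d: int  # post, not endorsed
    excluded: int = 0  # missing/invalid responses left out of the table

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class PatientRecord:
    """One admission; ``age_years`` is top-coded to 90 for ages 90+ (so no
    mean age is reported), ``gcs`` may be missing."""

    age_years: int
    age_top_coded: bool
    female: bool
    gcs: int | None
    icd10_chapter: str
    phase: Phase


def dichotomize(
    responses: list[LikertResponse],
    item_id: str,
    endorsed_levels: set[int],
    scale: set[int] | None = None,
) -> FourfoldTable:
    """Collapse one item's responses into a phase × endorsement table.

    ``scale`` declares the item's valid levels (default 1–5); endorsed
    levels outside the scale are a configuration error.  Responses with
    levels outside the scale are excluded and tallied, not counted.
    """
    scale = scale or {1, 2, 3, 4, 5}
    if not endorsed_levels <= scale:
        raise ValueError(
            f"endorsed levels {sorted(endorsed_levels - scale)} outside the item scale"
        )
    cells = {"a": 0, "b": 0, "c": 0, "d": 0}
    excluded = 0
    for r in responses:
        if r.item_id != item_id:
            continue
        if r.level not in scale:
            excluded += 1
            continue
        endorsed = r.level in endorsed_levels
        if r.phase == Phase.PRE:
            cells["a" if endorsed else "b"] += 1
        else:
            cells["c" if endorsed else "d"] += 1
    table = FourfoldTable(**cells, excluded=excluded)
    if table.n == 0:
        raise ValueError(f"no usable responses for item {item_id!r}")
    return table


def chi_square_2x2(t: FourfoldTable) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a fourfold table, df = 1.

    Equals the closed form n(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)).  No
    continuity correction is applied.
    """
    margins = [t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d]
    if t.n == 0 or any(m == 0 for m in margins):
        raise ValueError("degenerate table: a zero marginal")
    stat = t.n * (t.a * t.d - t.b * t.c) ** 2 / np.prod([float(m) for m in margins])
    return float(stat), float(stats.chi2.sf(stat, df=1))


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Valid with ties: enumerates all C(n, n_a) splits of the pooled
    midranks and counts splits with |U − n_a·n_b/2| at least as extreme.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, na = len(pooled), len(a)
    mu = na * (len(b)) / 2.0
    ra = ranks[:na].sum()
    u_obs = ra - na * (na + 1) / 2.0
    dev = abs(u_obs - mu)
    hits = 0
    for idx in combinations(range(n), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2.0
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return float(u_obs), hits / comb(n, na)


def rank_sum_test(a, b, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Midranks handle ties.  Exact enumeration is used when the pooled
    sample size is at most ``exact_max_n``; otherwise the normal
    approximation with tie correction.  Returns (U of the first sample,
    two-sided p).  Identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return float(a.size * b.size / 2.0), 1.0
    if a.size + b.size <= exact_max_n:
        return _exact_rank_sum_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def reconstruct_counts(percent: float, n: int) -> int:
    """Endorsement count implied by a printed percentage of n respondents."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent must lie in [0, 100]")
    return round_half_away(percent / 100.0 * n)


def fourfold_from_percentages(
    pct_pre: float, n_pre: int, pct_post: float, n_post: int
) -> FourfoldTable:
    """Rebuild a phase × endorsement table from printed percentages and Ns."""
    a = reconstruct_counts(pct_pre, n_pre)
    c = reconstruct_counts(pct_post, n_post)
    return FourfoldTable(a=a, b=n_pre - a, c=c, d=n_post - c)


# ---------------------------------------------------------------------------
# Patient-characteristic comparison
# ---------------------------------------------------------------------------

def compare_patients(records: list[PatientRecord]) -> dict[str, dict]:
    """Pre/post equivalence checks on patient characteristics.

    Gender and primary-diagnosis proportions use the chi-square test;
    age and GCS the rank-sum test on the (top-coded) ordinal scale.
    Means are reported for GCS only — top-coding makes a mean age
    meaningless.
    """
    pre = [r for r in records if r.phase == Phase.PRE]
    post = [r for r in records if r.phase == Phase.POST]
    if not pre or not post:
        raise ValueError("both phases need at least one patient record")
    out: dict[str, dict] = {}

    def binary_row(name: str, flag) -> None:
        t = FourfoldTable(
            a=sum(flag(r) for r in pre), b=sum(not flag(r) for r in pre),
            c=sum(flag(r) for r in post), d=sum(not flag(r) for r in post),
        )
        stat, p = chi_square_2x2(t)
        out[name] = {
            "n_pre": t.a, "pct_pre": 100.0 * t.a / (t.a + t.b),
            "n_post": t.c, "pct_post": 100.0 * t.c / (t.c + t.d),
            "test": "chi-square", "p": p,
        }

    binary_row("female", lambda r: r.female)
    for chapter in sorted({r.icd10_chapter for r in records}):
        binary_row(f"icd10_{chapter}", lambda r, ch=chapter: r.icd10_chapter == ch)

    ages_pre = [r.age_years for r in pre]
    ages_post = [r.age_years for r in post]
    _, p_age = rank_sum_test(ages_pre, ages_post)
    out["age"] = {
        "median_pre": float(np.median(ages_pre)),
        "median_post": float(np.median(ages_post)),
        "iqr_pre": tuple(np.percentile(ages_pre, [25, 75])),
        "iqr_post": tuple(np.percentile(ages_post, [25, 75])),
        "test": "rank-sum", "p": p_age,
    }
    gcs_pre = [r.gcs for r in pre if r.gcs is not None]
    gcs_post = [r.gcs for r in post if r.gcs is not None]
    if gcs_pre and gcs_post:
        _, p_gcs = rank_sum_test(gcs_pre, gcs_post)
        out["gcs"] = {
            "n_pre": len(gcs_pre), "n_post": len(gcs_post),
            "median_pre": float(np.median(gcs_pre)),
            "median_post": float(np.median(gcs_post)),
            "mean_pre": float(np.mean(gcs_pre)),
            "mean_post": float(np.mean(gcs_post)),
            "test": "rank-sum", "p": p_gcs,
        }
    return out
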