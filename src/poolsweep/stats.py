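"""Diversity, selection, repeatability and group-comparison statistics.

All statistics operate on a filtered :class:`~poolsweep.model.VariantTable`.

Expected heterozygosity (nucleotide diversity) per sample is
``pi = sum_sites 2 p (1-p) / L_eff`` where ``L_eff`` is the number of sites
reliably evaluated genome-wide (not just the variable ones), so pi is on the
per-site scale.

The effective selection coefficient of a variant in one replicate is the
per-generation log growth of its frequency relative to a lineage whose
frequency stays constant::

    s_eff = ln(f_end / f_start) / delta_g

with frequencies floored at the caller's detection threshold (default 0.002)
so alleles absent at the first time point get a finite, conservative
estimate. A logit-scale variant (``ln[(f/(1-f)) / (f0/(1-f0))]/delta_g``,
the classic Wright-Fisher invasion rate) is available via ``form="logit"``.

Repeatability of a variant is the number of replicates whose endpoint
(last sequenced time point) carries it at frequency > 0.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: generations per day: 52 days of evolution corresponded to ~75 generations
GEN_PER_DAY = 75.0 / 52.0

#: pooled caller detection threshold used as the frequency floor
F_FLOOR = 0.002


def diversity(table, L_eff: float = 3e5) -> pd.DataFrame:
    """Per-sample polymorphic-site count and expected heterozygosity.

    Missing frequency estimates are skipped per sample. Fixed alleles
    (af = 1) count as polymorphic relative to the reference but contribute
    zero heterozygosity.
    """
    if L_eff <= 0:
        raise ValueError("L_eff must be positive")
    af = table.af
    rows = []
    for j, s in enumerate(table.samples):
        p = af[:, j]
        p = p[~np.isnan(p)]
        rows.append(
            {
                "sample_id": s.sample_id,
                "replicate_id": s.replicate_id,
                "treatment": s.treatment.value,
                "day": s.day,
                "n_polymorphic": int((p > 0).sum()),
                "pi": float((2 * p * (1 - p)).sum() / L_eff),
            }
        )
    return pd.DataFrame(rows)


def selection_coefficient(
    f_start: float,
    f_end: float,
    delta_g: float,
    f_floor: float = F_FLOOR,
    form: str = "log_ratio",
) -> float:
    """Effective selection coefficient from two frequency observations."""
    if delta_g <= 0:
        raise ValueError("delta_g must be positive")
    if not (0 <= f_start <= 1 and 0 <= f_end <= 1):
        raise ValueError("frequencies must be in [0, 1]")
    f0 = max(f_start, f_floor)
    f1 = max(f_end, f_floor)
    if form == "log_ratio":
        return math.log(f1 / f0) / delta_g
    if form == "logit":
        f0 = min(f0, 1 - f_floor)
        f1 = min(f1, 1 - f_floor)
        return math.log((f1 / (1 - f1)) / (f0 / (1 - f0))) / delta_g
    raise ValueError(f"unknown form {form!r}")


def _replicate_bounds(table) -> dict[str, tuple[int, int]]:
    """Per replicate: (first, last) sample column index by day."""
    groups = table.replicate_samples(include_ancestors=False)
    return {rep: (cols[0], cols[-1]) for rep, cols in groups.items() if cols}


def selection_estimates(
    table,
    gen_per_day: float = GEN_PER_DAY,
    f_floor: float = F_FLOOR,
    form: str = "log_ratio",
) -> pd.DataFrame:
    """Per (site, replicate) effective selection coefficient.

    Start and end are each replicate's first and last sequenced time points;
    elapsed generations are (day_end - day_start) * gen_per_day. Rows where
    either frequency estimate is missing get NaN.
    """
    af = table.af
    rows = []
    for rep, (j0, j1) in _replicate_bounds(table).items():
        d0, d1 = table.samples[j0].day, table.samples[j1].day
        if d1 == d0:
            continue
        delta_g = (d1 - d0) * gen_per_day
        for i, site in enumerate(table.sites):
            f0, f1 = af[i, j0], af[i, j1]
            if np.isnan(f0) or np.isnan(f1):
                s_eff = math.nan
            else:
                s_eff = selection_coefficient(
                    f0, f1, delta_g, f_floor=f_floor, form=form
                )
            rows.append(
                {
                    "contig": site.contig,
                    "pos": site.pos,
                    "ref": site.ref_base,
                    "alt": site.alt_base,
                    "replicate_id": rep,
                    "f_start": f0,
                    "f_end": f1,
                    "delta_g": delta_g,
                    "s_eff": s_eff,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos",
            "ref",
            "alt",
            "replicate_id",
            "f_start",
            "f_end",
            "delta_g",
            "s_eff",
        ],
    )


def repeatability(
    table,
    gen_per_day: float = GEN_PER_DAY,
    f_floor: float = F_FLOOR,
    effect_classes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-site repeatability and mean effective selection coefficient.

    ``n_replicates_present`` counts replicates whose endpoint frequency is
    defined and > 0; ``mean_s_eff`` averages s_eff over those replicates
    only. ``effect_classes``, when given, must be one class label per site
    (in table order).
    """
    af = table.af
    bounds = _replicate_bounds(table)
    est = selection_estimates(table, gen_per_day=gen_per_day, f_floor=f_floor)
    s_by = {
        (r["pos"], r["alt"], r["replicate_id"]): r["s_eff"]
        for _, r in est.iterrows()
    }
    rows = []
    for i, site in enumerate(table.sites):
        present_reps = [
            rep
            for rep, (_, j1) in bounds.items()
            if not np.isnan(af[i, j1]) and af[i, j1] > 0
        ]
        s_vals = [
            s_by.get((site.pos, site.alt_base, rep), math.nan)
            for rep in present_reps
        ]
        s_vals = [s for s in s_vals if not math.isnan(s)]
        rows.append(
            {
                "contig": site.contig,
                "pos": site.pos,
                "ref": site.ref_base,
                "alt": site.alt_base,
                "n_replicates_present": len(present_reps),
                "mean_s_eff": float(np.mean(s_vals)) if s_vals else math.nan,
                "effect_class": (
                    effect_classes[i] if effect_classes is not None else None
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

#: at or below this combined sample size the Mann-Whitney branch is exact
EXACT_MW_LIMIT = 12


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x (mid-rank ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx = ranks[: len(x)].sum()
    return rx - len(x) * (len(x) + 1) / 2


def mannwhitney_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney test.

    Exact by enumeration of all label arrangements when n+m <= 12 (two-sided
    p = 2 * min tail of the permutation distribution of U, capped at 1);
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = len(x), len(y)
    if n + m <= EXACT_MW_LIMIT:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        u_obs = ranks[:n].sum() - n * (n + 1) / 2
        us = []
        for idx in itertools.combinations(range(n + m), n):
            us.append(ranks[list(idx)].sum() - n * (n + 1) / 2)
        us = np.asarray(us)
        tol = 1e-9
        lower = (us <= u_obs + tol).mean()
        upper = (us >= u_obs - tol).mean()
        return float(min(1.0, 2 * min(lower, upper)))
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def welch_t_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Welch unequal-variance t-test (Satterthwaite df), two-sided.

    Degenerate case: zero variance in both groups with equal means gives
    p = 1 (no evidence of difference).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 1.0
        return 0.0
    return float(sps.ttest_ind(x, y, equal_var=False).pvalue)


def poisson_loglinear_two_group(
    counts_a: Sequence[int], counts_b: Sequence[int]
) -> float:
    """Wald p-value for the group effect in a two-group Poisson log-linear
    model (identical to a GLM with log link and a group indicator).

    With totals A and B over n_a and n_b observations, the group coefficient
    is beta = ln(mean_b / mean_a) with SE = sqrt(1/A + 1/B).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("a group total of 0 leaves the coefficient unbounded")
    beta = math.log(b.mean() / a.mean())
    se = math.sqrt(1 / a.sum() + 1 / b.sum())
    return float(2 * sps.norm.sf(abs(beta) / se))


@dataclass
class ClassComparison:
    p_repeatability: float
    p_selection: float
    n_synonymous: int
    n_nonsynonymous: int


def class_comparison(records: pd.DataFrame) -> ClassComparison:
    """Compare synonymous vs nonsynonymous variants.

    Repeatability (replicate counts) is compared with the Mann-Whitney test;
    mean effective selection coefficients with Welch's t-test. Intergenic and
    start/stop classes are excluded (their typical fitness effects are less
    clear). A class with fewer than 2 records leaves the corresponding
    p-value NaN with a warning.
    """
    syn = records[records["effect_class"] == "synonymous"]
    non = records[records["effect_class"] == "nonsynonymous"]
    p_rep = p_sel = math.nan
    if len(syn) < 2 or len(non) < 2:
        warnings.warn(
            f"class comparison undefined: {len(syn)} synonymous / "
            f"{len(non)} nonsynonymous records (need >= 2 each)",
            stacklevel=2,
        )
    else:
        p_rep = mannwhitney_two_sided(
            non["n_replicates_present"], syn["n_replicates_present"]
        )
        sel_n = non["mean_s_eff"].dropna()
        sel_s = syn["mean_s_eff"].dropna()
        if len(sel_n) >= 2 and len(sel_s) >= 2:
            p_sel = welch_t_two_sided(sel_n, sel_s)
        else:
            warnings.warn(
                "selection comparison undefined: fewer than 2 finite "
                "mean_s_eff per class",
                stacklevel=2,
            )
    return ClassComparison(
        p_repeatability=p_rep,
        p_selection=p_sel,
        n_synonymous=len(syn),
        n_nonsynonymous=len(non),
    )


__all__ = [
    "GEN_PER_DAY",
    "F_FLOOR",
    "diversity",
    "selection_coefficient",
    "selection_estimates",
    "repeatability",
    "mannwhitney_two_sided",
    "welch_t_two_sided",
    "poisson_loglinear_two_group",
    "ClassComparison",
    "class_comparison",
]
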