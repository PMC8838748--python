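"""Post-calling artifact filters for pooled time-series variant calls.

Pooled calls from an evolve-and-resequence experiment carry characteristic
artifacts. Under strong directional selection in a clonal genome, a genuine
polymorphism cannot sit at a constant frequency through time, so a variant
whose trajectory is statistically indistinguishable from repeated draws of a
single binomial is treated as an artifact (mapping error, paralogy).
Likewise, a locus that is polymorphic at intermediate frequency in *every*
population of a sequencing batch is far more plausibly a batch-level mapping
artifact than parallel biology.

Three flags, each computed independently on the QUAL-passing table:

* ``excess_missing`` — more than ``max_missing_fraction`` of samples have no
  frequency estimate (depth below the table's ``min_depth``);
* ``constant_binomial`` — within every replicate the trajectory is consistent
  with one binomial success probability (exact two-sided test per time point,
  Benjamini-Hochberg over the site's pooled tests, no q-value below
  ``fdr_alpha``);
* ``ubiquitous_polymorphic`` — in at least one batch with two or more
  informative samples, every frequency estimate lies in
  (``af_lower``, ``af_upper``].

A site is retained iff it carries no flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import VariantTable

# relative slop when comparing pmf values in the minimum-likelihood rule,
# so ties are not broken by floating-point noise
_MINLIKE_EPS = 1e-7


@dataclass
class FilterConfig:
    """Thresholds for the artifact-filter cascade (defaults as in the study
    design: QUAL 20, 10% missing data, FDR 0.05, polymorphism bounds
    (0.01, 0.99])."""

    min_qual: float = 20.0
    max_missing_fraction: float = 0.10
    fdr_alpha: float = 0.05
    af_lower: float = 0.01
    af_upper: float = 0.99

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if not self.af_lower < self.af_upper:
            raise ValueError("af_lower must be < af_upper")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in [0, 1]")


@dataclass
class FilterReport:
    """Per-site flags plus the per-(site, replicate, time point) test table.

    ``site_flags`` columns: contig, pos, ref, alt, qual, low_qual,
    excess_missing, constant_binomial, ubiquitous_polymorphic, retained.
    ``tests`` columns: contig, pos, ref, alt, replicate_id, day, alt_count,
    depth, p_value, q_value.
    """

    site_flags: pd.DataFrame
    tests: pd.DataFrame = field(default_factory=pd.DataFrame)

    def removal_counts(self) -> dict[str, int]:
        f = self.site_flags
        return {
            "low_qual": int(f["low_qual"].sum()),
            "excess_missing": int(f["excess_missing"].sum()),
            "constant_binomial": int(f["constant_binomial"].sum()),
            "ubiquitous_polymorphic": int(f["ubiquitous_polymorphic"].sum()),
            "retained": int(f["retained"].sum()),
        }

    def to_tsv(self, flags_path: str, tests_path: Optional[str] = None) -> None:
        self.site_flags.to_csv(flags_path, sep="\t", index=False)
        if tests_path is not None:
            self.tests.to_csv(tests_path, sep="\t", index=False)


def binom_minlike_pvalue(k: int, n: int, p: float) -> float:
    """Exact two-sided binomial p-value, minimum-likelihood convention.

    The p-value is the total probability of all outcomes whose probability
    under Binomial(n, p) does not exceed that of the observed outcome
    (up to a small relative tolerance). This is the convention of the
    standard exact binomial test in mainstream statistical software.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 <= p <= 1:
        raise ValueError("need 0 <= p <= 1")
    if p == 0:
        return 1.0 if k == 0 else 0.0
    if p == 1:
        return 1.0 if k == n else 0.0
    pmf = stats.binom.pmf(np.arange(n + 1), n, p)
    cutoff = pmf[k] * (1 + _MINLIKE_EPS)
    return float(min(1.0, pmf[pmf <= cutoff].sum()))


def binomial_constancy_test(
    trajectory: Sequence[tuple[int, int]],
) -> list[float]:
    """Test each time point of one replicate's trajectory for consistency
    with a single binomial success probability.

    ``trajectory`` is a list of (alt_count, depth) pairs; pairs with zero
    depth contribute no test. The pooled success probability is
    sum(alt)/sum(depth) over the same pairs; each time point then gets an
    exact two-sided binomial p-value against it. Returns one p-value per
    positive-depth time point (empty list if none).
    """
    observed = [(int(a), int(d)) for a, d in trajectory if d > 0]
    if not observed:
        return []
    total_alt = sum(a for a, _ in observed)
    total_depth = sum(d for _, d in observed)
    p_hat = total_alt / total_depth
    return [binom_minlike_pvalue(a, d, p_hat) for a, d in observed]


def filter_missing(table: VariantTable, cfg: FilterConfig) -> np.ndarray:
    """Flag sites with more than floor(max_missing_fraction * n_samples)
    missing frequency estimates (e.g. "more than 3 of 35" at 10%)."""
    n_missing = np.isnan(table.af).sum(axis=1)
    allowed = math.floor(cfg.max_missing_fraction * table.n_samples)
    return n_missing > allowed


def filter_constant(
    table: VariantTable, cfg: FilterConfig
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag sites with no evidence of frequency change in any replicate.

    For each site, exact binomial p-values are collected over all replicates
    and time points (ancestor samples excluded), Benjamini-Hochberg adjusted
    within the site, and the site is flagged for removal iff no adjusted
    q-value falls below ``fdr_alpha``. Returns the per-site flag vector and
    the tidy per-test table.
    """
    replicates = table.replicate_samples(include_ancestors=False)
    flags = np.zeros(table.n_sites, dtype=bool)
    rows: list[dict] = []
    for i, site in enumerate(table.sites):
        pvals: list[float] = []
        meta: list[tuple[str, int, int, int]] = []
        for rep_id, cols in replicates.items():
            traj = [
                (table.alt_counts[i, j], table.depth[i, j]) for j in cols
            ]
            kept = [(j, a, d) for j, (a, d) in zip(cols, traj) if d > 0]
            ps = binomial_constancy_test(traj)
            for (j, a, d), p in zip(kept, ps):
                pvals.append(p)
                meta.append((rep_id, table.samples[j].day, a, d))
        if pvals:
            qvals = multipletests(pvals, method="fdr_bh")[1]
            flags[i] = not (qvals < cfg.fdr_alpha).any()
        else:
            qvals = np.array([])
            flags[i] = True  # nothing observed anywhere: no evidence of change
        for (rep_id, day, a, d), p, q in zip(meta, pvals, qvals):
            rows.append(
                {
                    "contig": site.contig,
                    "pos": site.pos,
                    "ref": site.ref_base,
                    "alt": site.alt_base,
                    "replicate_id": rep_id,
                    "day": day,
                    "alt_count": a,
                    "depth": d,
                    "p_value": p,
                    "q_value": q,
                }
            )
    tests = pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos",
            "ref",
            "alt",
            "replicate_id",
            "day",
            "alt_count",
            "depth",
            "p_value",
            "q_value",
        ],
    )
    return flags, tests


def filter_ubiquitous_polymorphism(
    table: VariantTable, cfg: FilterConfig
) -> np.ndarray:
    """Flag sites polymorphic in every informative sample of some batch.

    A sample is "polymorphic" at the site when its frequency estimate lies in
    (``af_lower``, ``af_upper``]. The flag fires when at least one batch with
    >= 2 non-missing samples is entirely polymorphic; missing estimates are
    skipped and a single observation cannot establish batch-wide consistency.
    """
    af = table.af
    flags = np.zeros(table.n_sites, dtype=bool)
    for _, cols in table.batch_samples().items():
        sub = af[:, cols]
        informative = ~np.isnan(sub)
        n_inf = informative.sum(axis=1)
        poly = (sub > cfg.af_lower) & (sub <= cfg.af_upper)
        all_poly = np.where(informative, poly, True).all(axis=1)
        flags |= (n_inf >= 2) & all_poly
    return flags


def apply_filter_cascade(
    table: VariantTable, cfg: Optional[FilterConfig] = None
) -> tuple[VariantTable, FilterReport]:
    """Run all filters and return (retained table, full report).

    The QUAL threshold is applied first; the three artifact flags are then
    computed independently on the QUAL-passing sites, so a site may carry
    several flags and per-criterion removal counts overlap (as they do when
    the cascade is applied to real pooled call sets). Retained sites are
    exactly the unflagged ones, the same set a sequential cascade would keep.
    """
    cfg = cfg or FilterConfig()
    quals = np.array([s.qual for s in table.sites])
    low_qual = quals < cfg.min_qual
    passing = table.subset_sites(~low_qual)

    miss = filter_missing(passing, cfg)
    const, tests = filter_constant(passing, cfg)
    ubiq = filter_ubiquitous_polymorphism(passing, cfg)

    # scatter the passing-table flags back to the full site list
    n = table.n_sites
    excess_missing = np.zeros(n, dtype=bool)
    constant_binomial = np.zeros(n, dtype=bool)
    ubiquitous = np.zeros(n, dtype=bool)
    excess_missing[~low_qual] = miss
    constant_binomial[~low_qual] = const
    ubiquitous[~low_qual] = ubiq
    retained = ~(low_qual | excess_missing | constant_binomial | ubiquitous)

    site_flags = pd.DataFrame(
        {
            "contig": [s.contig for s in table.sites],
            "pos": [s.pos for s in table.sites],
            "ref": [s.ref_base for s in table.sites],
            "alt": [s.alt_base for s in table.sites],
            "qual": quals,
            "low_qual": low_qual,
            "excess_missing": excess_missing,
            "constant_binomial": constant_binomial,
            "ubiquitous_polymorphic": ubiquitous,
            "retained": retained,
        }
    )
    report = FilterReport(site_flags=site_flags, tests=tests)
    return table.subset_sites(retained), report


__all__ = [
    "FilterConfig",
    "FilterReport",
    "binom_minlike_pvalue",
    "binomial_constancy_test",
    "filter_missing",
    "filter_constant",
    "filter_ubiquitous_polymorphism",
    "apply_filter_cascade",
]
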