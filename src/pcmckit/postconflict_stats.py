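"""Nonparametric, survival and stress-proxy analyses of PC/MC data.

* Paired Wilcoxon signed-rank tests per focal individual (exact
  enumeration of the tie-corrected signed-rank distribution for small
  samples, normal approximation with tie correction otherwise; zero
  differences are dropped before ranking).
* Kaplan-Meier / log-rank (Mantel-Cox) comparison of first-contact
  latencies between PC and MC follows, right-censored at the 600-s follow
  end, one observation per follow.
* Self-directed behaviour rates — self-scratching in bouts/min and
  self-grooming in seconds/min — by post-conflict outcome category, with
  the three planned pairwise comparisons Bonferroni-corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .ethogram_io import Dataset
from .pcmc import ATTRACTED, PairRecord

#: sample size up to which the exact signed-rank distribution is enumerated
EXACT_WILCOXON_N = 40


@dataclass(frozen=True)
class WilcoxonResult:
    z: float
    p: float
    n_effective: int
    w_plus: float
    method: str  # exact | normal | undefined

    @property
    def undefined(self) -> bool:
        return self.method == "undefined"


def _signed_rank_distribution(ranks2: Sequence[int]) -> np.ndarray:
    """PMF support array of W+ over all sign assignments (ranks doubled to ints)."""
    total = sum(ranks2)
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_paired(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_threshold: int = EXACT_WILCOXON_N,
) -> WilcoxonResult:
    """Two-tailed paired Wilcoxon signed-rank test.

    Pairs with zero difference are dropped before ranking.  For
    ``n <= exact_threshold`` the p-value comes from the exact distribution
    of W+ over all 2**n sign patterns of the (tie-corrected) ranks; larger
    samples use the normal approximation with tie correction and no
    continuity correction.  The Z statistic is always reported on the
    normal scale, signed so that ``a`` systematically below ``b`` gives a
    negative Z.  Fewer than two informative pairs leaves the test
    undefined (reported as Z = 0, p = 1, flagged via ``method``).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n < 2:
        return WilcoxonResult(0.0, 1.0, n, 0.0, "undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    z = 0.0 if var == 0 else (w_plus - mean) / math.sqrt(var)
    if n <= exact_threshold:
        ranks2 = np.rint(ranks * 2).astype(int)
        pmf = _signed_rank_distribution(ranks2)
        w2 = int(round(w_plus * 2))
        lower = pmf[: w2 + 1].sum()
        upper = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(lower, upper))
        method = "exact"
    else:
        p = 2.0 * sps.norm.sf(abs(z))
        method = "normal"
    return WilcoxonResult(z, float(p), n, w_plus, method)


# ---------------------------------------------------------------------------
# survival comparison of first-contact latencies
# ---------------------------------------------------------------------------


@dataclass
class LogrankResult:
    chi2: float
    p: float
    df: int
    n_pc: int
    n_mc: int
    km_pc: Optional[pd.DataFrame] = None
    km_mc: Optional[pd.DataFrame] = None


def latency_samples(records: Iterable[PairRecord],
                    duration_s: float = 600.0) -> pd.DataFrame:
    """Long-format latency table (condition, duration, observed) from labels."""
    rows = []
    for r in records:
        for cond, lat in (("PC", r.pc_latency), ("MC", r.mc_latency)):
            rows.append(
                {
                    "condition": cond,
                    "duration": lat if lat is not None else duration_s,
                    "observed": int(lat is not None),
                }
            )
    return pd.DataFrame(rows)


def logrank_compare(records: Iterable[PairRecord],
                    duration_s: float = 600.0,
                    fit_curves: bool = True) -> LogrankResult:
    """Mantel-Cox comparison of PC vs MC first-contact latencies.

    All-censored arms leave the statistic undefined (raises ValueError).
    """
    df = latency_samples(records, duration_s)
    if df.empty:
        raise ValueError("no latency observations")
    pc = df[df["condition"] == "PC"]
    mc = df[df["condition"] == "MC"]
    if pc["observed"].sum() == 0 and mc["observed"].sum() == 0:
        raise ValueError("log-rank undefined: all observations censored")
    res = logrank_test(pc["duration"], mc["duration"],
                       event_observed_A=pc["observed"],
                       event_observed_B=mc["observed"])
    km_pc = km_mc = None
    if fit_curves:
        kmf = KaplanMeierFitter()
        kmf.fit(pc["duration"], pc["observed"], label="PC")
        km_pc = kmf.survival_function_
        kmf = KaplanMeierFitter()
        kmf.fit(mc["duration"], mc["observed"], label="MC")
        km_mc = kmf.survival_function_
    return LogrankResult(float(res.test_statistic), float(res.p_value), 1,
                         len(pc), len(mc), km_pc, km_mc)


# ---------------------------------------------------------------------------
# multiple-comparison control
# ---------------------------------------------------------------------------


def bonferroni_alpha(nominal: float = 0.05, n_comparisons: int = 3,
                     decimals: int = 3) -> float:
    """Bonferroni-corrected alpha, truncated to ``decimals`` places.

    Truncation (not rounding) reproduces the conventional reporting of
    0.05/3 as 0.016.
    """
    corrected = nominal / n_comparisons
    scale = 10 ** decimals
    return math.floor(corrected * scale) / scale


# ---------------------------------------------------------------------------
# self-directed behaviour (stress proxies)
# ---------------------------------------------------------------------------

STRESS_CONDITIONS = (
    "MC", "PC_no_affiliation", "PC_consolation", "PC_reconciliation", "PC_both",
)

#: planned pairwise comparisons; alpha is Bonferroni-corrected for these three
STRESS_COMPARISONS = (
    ("MC", "PC_no_affiliation"),
    ("MC", "PC_consolation"),
    ("PC_no_affiliation", "PC_consolation"),
)


def _follow_rates(follow) -> tuple[float, float]:
    minutes = follow.duration_s / 60.0
    scratch = sum(1 for s in follow.self_directed if s.kind == "scratch_bout")
    groom = sum(s.duration_s for s in follow.self_directed if s.kind == "groom_interval")
    return scratch / minutes, groom / minutes


@dataclass
class StressReport:
    rates: pd.DataFrame                      # focal x condition mean rates
    condition_means: pd.DataFrame            # grand means per condition
    outcome_counts: dict[str, int]           # PC category tallies
    comparisons: pd.DataFrame                # pairwise Wilcoxon results
    alpha_corrected: float = field(default_factory=bonferroni_alpha)


def categorize_outcomes(consolation_records: Iterable[PairRecord],
                        reconciliation_records: Iterable[PairRecord]) -> dict[int, str]:
    """Map conflict id -> PC outcome category from the two label streams."""
    consol = {r.conflict_id: r.label == ATTRACTED for r in consolation_records}
    recon = {r.conflict_id: r.label == ATTRACTED for r in reconciliation_records}
    out = {}
    for cid in consol:
        c, r = consol[cid], recon.get(cid, False)
        if c and r:
            out[cid] = "PC_both"
        elif c:
            out[cid] = "PC_consolation"
        elif r:
            out[cid] = "PC_reconciliation"
        else:
            out[cid] = "PC_no_affiliation"
    return out


def stress_rates(
    dataset: Dataset,
    consolation_records: Iterable[PairRecord],
    reconciliation_records: Iterable[PairRecord],
    measure: str = "scratch",
) -> StressReport:
    """Self-directed behaviour rates by outcome category + paired comparisons.

    Following the confound-control convention, the PC-with-consolation and
    PC-without-affiliation cells exclude follows in which reconciliation
    also occurred.  Comparisons are per-focal paired Wilcoxon tests on
    focals contributing to both cells, at the Bonferroni-corrected alpha.
    """
    categories = categorize_outcomes(consolation_records, reconciliation_records)
    rows = []
    for conflict, pc, mc in dataset.retained_pairs():
        cat = categories.get(conflict.conflict_id)
        if cat is None:
            continue
        scratch, groom = _follow_rates(pc)
        rows.append({"focal_id": pc.focal_id, "condition": cat,
                     "scratch_rate": scratch, "groom_rate": groom})
        scratch, groom = _follow_rates(mc)
        rows.append({"focal_id": mc.focal_id, "condition": "MC",
                     "scratch_rate": scratch, "groom_rate": groom})
    long = pd.DataFrame(rows)
    counts = {c: 0 for c in STRESS_CONDITIONS if c != "MC"}
    for cat in categories.values():
        counts[cat] = counts.get(cat, 0) + 1
    if long.empty:
        return StressReport(long, long, counts,
                            pd.DataFrame(columns=["condition_a", "condition_b", "z",
                                                  "p", "n", "significant"]))
    rates = long.groupby(["focal_id", "condition"]).mean(numeric_only=True)
    condition_means = long.groupby("condition").mean(numeric_only=True)
    col = f"{measure}_rate"
    wide = rates[col].unstack("condition")
    alpha = bonferroni_alpha()
    comp_rows = []
    for ca, cb in STRESS_COMPARISONS:
        if ca not in wide.columns or cb not in wide.columns:
            comp_rows.append({"condition_a": ca, "condition_b": cb, "z": np.nan,
                              "p": np.nan, "n": 0, "significant": False})
            continue
        paired = wide[[ca, cb]].dropna()
        res = wilcoxon_paired(paired[ca], paired[cb])
        comp_rows.append({"condition_a": ca, "condition_b": cb, "z": res.z,
                          "p": res.p, "n": len(paired),
                          "significant": (not res.undefined) and res.p < alpha})
    return StressReport(rates, condition_means, counts, pd.DataFrame(comp_rows), alpha)


def mc_contact_control(dataset: Dataset) -> tuple[WilcoxonResult, pd.DataFrame]:
    """Scratch rates in MCs with vs without received affiliative contact.

    A control for whether contact per se (outside any conflict context)
    lowers arousal: per-focal mean scratch rates are compared between MC
    follows in which the focal received contact and those in which it did
    not, with a paired Wilcoxon test.
    """
    rows = []
    for _conflict, _pc, mc in dataset.retained_pairs():
        received = any(c.recipient_id == mc.focal_id for c in mc.contacts)
        scratch, _ = _follow_rates(mc)
        rows.append({"focal_id": mc.focal_id,
                     "condition": "contact" if received else "no_contact",
                     "scratch_rate": scratch})
    df = pd.DataFrame(rows)
    if df.empty or df["condition"].nunique() < 2:
        return WilcoxonResult(0.0, 1.0, 0, 0.0, "undefined"), df
    wide = (
        df.groupby(["focal_id", "condition"])["scratch_rate"].mean()
        .unstack("condition").dropna()
    )
    if len(wide) < 2:
        return WilcoxonResult(0.0, 1.0, len(wide), 0.0, "undefined"), df
    return wilcoxon_paired(wide["contact"], wide["no_contact"]), df
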