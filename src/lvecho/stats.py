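"""Paired nonparametric and parametric tests used to compare contrast doses.

Three procedures cover the study's comparisons:

* :func:`wilcoxon_signed_rank` — paired ordinal segment scores (exact sign
  enumeration for small effective n, tie/continuity-corrected normal
  approximation otherwise);
* :func:`mcnemar` — paired binary indicators of Dice-bin membership (exact
  binomial for few discordant pairs, 1-df chi-square otherwise);
* :func:`paired_t` — relative physiological differences around an injection,
  with a 95% confidence interval.

All tests are two-sided and return a :class:`TestResult` carrying the raw
p-value plus a method note stating which computation branch was used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

PHYSIO_VARIABLES = ("sao2", "hr", "map")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_effective: int
    method_note: str
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class PhysioLog:
    """Per-minute SaO2 (%), heart rate (bpm) and mean arterial pressure (mmHg).

    ``samples`` is long on animals: columns (animal, t_min, sao2, hr, map).
    ``injections`` lists (dose_label, t_min) events shared by all animals.
    """

    samples: pd.DataFrame
    injections: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        need = {"animal", "t_min", "sao2", "hr", "map"}
        if not need <= set(self.samples.columns):
            raise ValueError(f"physio log missing columns: {sorted(need - set(self.samples.columns))}")
        for animal, grp in self.samples.groupby("animal"):
            t = grp["t_min"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"minutes not strictly increasing for animal {animal}")

    def to_csv(self, path) -> None:
        df = self.samples.copy()
        inj_minutes = {t for _, t in self.injections}
        df["injection"] = df["t_min"].isin(inj_minutes).astype(int)
        df.to_csv(path, index=False)


def significance_band(p: float) -> str:
    """Summary band used in the dose-comparison tables (raw p always kept)."""
    if p < 0.001:
        return "P<0.001"
    if p < 0.05:
        return "P<0.05"
    return "NS"


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def wilcoxon_signed_rank(
    pairs,
    zero_method: str = "discard",
    exact_threshold: int = 12,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired (a, b) observations.

    Differences d = a − b; zero differences are discarded (classical
    treatment; ``zero_method="pratt"`` keeps them in the ranking). Ties among
    |d| are mid-ranked. For n_effective ≤ ``exact_threshold`` the p-value is
    exact, by enumeration of all 2^n sign assignments of the ranks (valid
    under ties); otherwise a normal approximation with tie and continuity
    corrections is used.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one pair")
    if zero_method not in ("discard", "pratt"):
        raise ValueError("zero_method must be 'discard' or 'pratt'")
    d = np.asarray([float(a) - float(b) for a, b in pairs])
    nonzero = d != 0
    n_eff = int(nonzero.sum())
    if n_eff == 0:
        return TestResult(0.0, 1.0, 0, "all-zero differences")

    if zero_method == "discard":
        dd = d[nonzero]
        ranks = sps.rankdata(np.abs(dd))
        w_plus = float(ranks[dd > 0].sum())
        if n_eff <= exact_threshold:
            p = _exact_signed_rank_p(ranks, w_plus)
            return TestResult(w_plus, p, n_eff, "exact sign-assignment enumeration")
        mean = n_eff * (n_eff + 1) / 4.0
        var = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0
    else:  # pratt: rank |d| including zeros, drop the zeros' ranks from W
        ranks_all = sps.rankdata(np.abs(d))
        w_plus = float(ranks_all[d > 0].sum())
        n = len(d)
        n0 = n - n_eff
        mean = (n * (n + 1) - n0 * (n0 + 1)) / 4.0
        var = (n * (n + 1) * (2 * n + 1) - n0 * (n0 + 1) * (2 * n0 + 1)) / 24.0
        ranks = ranks_all[nonzero]

    # tie correction over groups of tied |d| (nonzero part)
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        return TestResult(w_plus, 1.0, n_eff, "degenerate variance (all ranks tied)")
    z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)  # continuity correction
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    note = "normal approximation, tie and continuity corrected"
    if zero_method == "pratt":
        note += ", Pratt zero handling"
    return TestResult(w_plus, p, n_eff, note)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by full enumeration of sign assignments of the ranks."""
    n = len(ranks)
    signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    w = signs @ ranks
    tol = 1e-9
    p_le = np.mean(w <= w_plus + tol)
    p_ge = np.mean(w >= w_plus - tol)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# McNemar


def mcnemar(pairs, exact_threshold: int = 25) -> TestResult:
    """Two-sided McNemar test on paired binary indicators (x, y).

    Uses the discordant counts b = #{x=1, y=0} and c = #{x=0, y=1}. Exact
    binomial p = min(1, 2·P(Bin(b+c, ½) ≤ min(b, c))) when b+c ≤
    ``exact_threshold``; otherwise the chi-square statistic (b−c)²/(b+c) with
    1 df. The method note reports the companion p-value of the other branch.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one pair")
    x = np.asarray([int(bool(a)) for a, _ in pairs])
    y = np.asarray([int(bool(b)) for _, b in pairs])
    if not (set(np.unique(x)) <= {0, 1} and set(np.unique(y)) <= {0, 1}):
        raise ValueError("pairs must be binary")
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    n_disc = b + c
    if n_disc == 0:
        return TestResult(0.0, 1.0, 0, "no discordant pairs")
    p_exact = min(1.0, 2.0 * sps.binom.cdf(min(b, c), n_disc, 0.5))
    chi2 = (b - c) ** 2 / n_disc
    p_chi2 = float(sps.chi2.sf(chi2, df=1))
    if n_disc <= exact_threshold:
        return TestResult(
            float(min(b, c)),
            p_exact,
            n_disc,
            f"exact binomial (b={b}, c={c}); chi-square p={p_chi2:.4g}",
        )
    return TestResult(
        float(chi2),
        p_chi2,
        n_disc,
        f"chi-square 1 df (b={b}, c={c}); exact binomial p={p_exact:.4g}",
    )


def bin_indicators(bins, target_bin) -> list[int]:
    """One-vs-rest binary indicators of membership in ``target_bin``."""
    return [int(b == target_bin) for b in bins]


# ---------------------------------------------------------------------------
# Physiology


def physio_effect(log: PhysioLog, dose, window_min: int = 3) -> pd.DataFrame:
    """Relative difference (%) of each variable across an injection.

    For every animal and variable: 100·(mean(after) − mean(before))/mean(before),
    where the windows are the ``window_min`` minutes strictly before and after
    the injection minute (the injection minute itself is excluded).
    """
    inj = [t for d, t in log.injections if d == dose]
    if not inj:
        raise ValueError(f"no injection recorded for dose {dose!r}")
    t_inj = inj[0]
    out = []
    for animal, grp in log.samples.groupby("animal"):
        t = grp["t_min"].to_numpy()
        before = grp[(t >= t_inj - window_min) & (t < t_inj)]
        after = grp[(t > t_inj) & (t <= t_inj + window_min)]
        if len(before) < window_min or len(after) < window_min:
            raise ValueError(
                f"insufficient samples around injection of dose {dose!r} "
                f"for animal {animal}"
            )
        for var in PHYSIO_VARIABLES:
            mb = float(before[var].mean())
            ma = float(after[var].mean())
            if mb == 0:
                raise ValueError(f"zero pre-injection mean for {var}, animal {animal}")
            out.append(
                {
                    "animal": animal,
                    "variable": var,
                    "rel_diff_pct": 100.0 * (ma - mb) / mb,
                }
            )
    return pd.DataFrame(out)


def paired_t(diffs) -> TestResult:
    """Two-sided one-sample t test on paired differences, with 95% CI."""
    d = np.asarray(list(diffs), dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least two differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0:
        p = 1.0 if mean == 0 else 0.0
        return TestResult(
            np.inf if mean else 0.0,
            p,
            n,
            "zero variance — degenerate CI",
            ci_low=mean,
            ci_high=mean,
        )
    se = sd / np.sqrt(n)
    t = mean / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(0.975, df))
    return TestResult(
        t, p, n, f"paired two-sided t, df={df}", ci_low=mean - tcrit * se, ci_high=mean + tcrit * se
    )
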