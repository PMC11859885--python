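"""Phenotype statistics for the salt-tolerance screen.

* leaf salt injury index (LSI): five per-plant damage levels 0 (healthy) to
  4 (dead or nearly dead) aggregated to a 0-100 % score,
  LSI = 100 * sum(k * n_k) / (4 N);
* relative salt injury rate (RSIR) of a grain trait measured under control
  (CK) and NaCl field conditions, RSIR = 100 * (X_CK - X_NaCl) / X_CK;
* qPCR relative expression via dCT = CT(target) - CT(reference) and
  2^-dCT;
* the two-sided Welch t comparison with the usual significance star codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass(frozen=True)
class InjuryCounts:
    """Plants per damage level in one scoring experiment; n0+..+n4 = N > 0."""

    n0: int
    n1: int
    n2: int
    n3: int
    n4: int

    def __post_init__(self):
        counts = self.as_tuple()
        if any(c < 0 or int(c) != c for c in counts):
            raise ValueError("injury counts must be nonnegative integers")
        if sum(counts) == 0:
            raise ValueError("no plants scored (N = 0)")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.n0, self.n1, self.n2, self.n3, self.n4)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


def lsi(counts: InjuryCounts, total: int | None = None) -> float:
    """Leaf salt injury index in percent, in [0, 100].

    ``total`` may restate N as a cross-check; a mismatch with the level
    counts is an error.
    """
    if total is not None and total != counts.total:
        raise ValueError(f"counts sum to {counts.total}, not the stated N={total}")
    weighted = sum(k * n for k, n in enumerate(counts.as_tuple()))
    return 100.0 * weighted / (4 * counts.total)


def lsi_mean(experiments) -> float:
    """LSI averaged over repeated scoring experiments (typically three)."""
    values = [lsi(e) for e in experiments]
    if not values:
        raise ValueError("no experiments")
    return float(np.mean(values))


def rsir(x_ck: float, x_nacl: float) -> float:
    """Relative salt injury rate (%): trait loss under salt relative to control.

    Negative when the salted trait exceeds the control (reported, never
    clipped); requires a positive control value.
    """
    if x_ck <= 0:
        raise ValueError("control trait value must be positive")
    return 100.0 * (x_ck - x_nacl) / x_ck


def delta_ct(ct_target: float, ct_ref: float) -> tuple[float, float]:
    """(dCT, relative expression 2^-dCT) from target/reference cycle thresholds."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_ref)):
        raise ValueError("cycle thresholds must be finite")
    d = float(ct_target) - float(ct_ref)
    return d, float(2.0 ** (-d))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    stars: str


def star_code(p: float) -> str:
    for threshold, code in STAR_THRESHOLDS:
        if p < threshold:
            return code
    return "ns"


def welch_t(group_a, group_b) -> WelchResult:
    """Two-sided Welch t test between two samples.

    Symmetric in group order up to the sign of t.  Both-sides-constant input
    is degenerate (no variance to test against) and raises.
    """
    a = np.asarray(list(group_a), float)
    b = np.asarray(list(group_b), float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("degenerate groups: zero variance on both sides")
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=p,
                       stars=star_code(p))
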