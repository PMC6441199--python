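"""Length- and depth-adjusted conditional binomial exact test.

For an orthologous gene pair with counts ``(x1, x2)``, lengths ``(L1, L2)``
and per-species orthologous sequencing depths ``(N1, N2)``, the counts are
modelled as independent Poisson variables.  Conditional on the pair total
``n = x1 + x2``, the species-1 count is Binomial(n, p0) under the null
hypothesis of equal expression level, with

    p0 = c*L1*N1 / (L2*N2 + c*L1*N1),

where ``c = S2/S1`` is the scaling factor that places the two species'
total expression outputs on a common scale (the SAGE-style exact test,
adjusted for cross-species gene-length and depth differences).  The
two-sided p-value is the probability of a deviation from the conditional
expectation ``n*p0`` at least as large as observed:

    p = P(|X - n*p0| >= |x1 - n*p0|),   X ~ Binomial(n, p0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["null_probability", "exact_pvalue", "test_all", "TestResult",
           "write_test_results"]

# Absolute slack (scaled by n) on the qualifying-set comparison
# |k - n*p0| >= |x1 - n*p0|, so the observed outcome is always included
# under floating-point rounding.
BOUNDARY_SLACK = 1e-9


def null_probability(L1, L2, N1, N2, c):
    """Binomial success probability for species 1 under the null.

    p0 = c*L1*N1 / (L2*N2 + c*L1*N1).  Accepts scalars or arrays
    (broadcast); lengths must be >= 1, depths >= 1 and c > 0.
    """
    L1 = np.asarray(L1, dtype=float)
    L2 = np.asarray(L2, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("scaling factor c must be > 0")
    if np.any(L1 < 1) or np.any(L2 < 1):
        raise ValueError("gene lengths must be >= 1")
    if N1 < 1 or N2 < 1:
        raise ValueError("sequencing depths must be >= 1")
    a = c * L1 * float(N1)
    b = L2 * float(N2)
    p0 = a / (b + a)
    return p0 if p0.ndim else float(p0)


def _pvalues(x1, n, p0):
    """Vectorised two-sided conditional binomial p-values.

    All arguments broadcast; returns an array of the broadcast shape.
    Tail masses are taken from the binomial CDF / survival function rather
    than accumulating pmf terms, so large totals stay accurate.
    """
    x1 = np.asarray(x1, dtype=float)
    n = np.asarray(n, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    mu = n * p0
    dev = np.abs(x1 - mu)
    thresh = dev - BOUNDARY_SLACK * n
    # qualifying outcomes: k <= mu - thresh  or  k >= mu + thresh
    lo = np.floor(mu - thresh)
    hi = np.ceil(mu + thresh)
    with np.errstate(invalid="ignore"):
        p = stats.binom.cdf(lo, n, p0) + stats.binom.sf(hi - 1.0, n, p0)
    # zero observed deviation (or n == 0): every outcome qualifies
    p = np.where((thresh <= 0) | (n == 0), 1.0, p)
    return np.clip(p, 0.0, 1.0)


def exact_pvalue(x1: int, x2: int, p0: float) -> float:
    """Two-sided exact p-value for one gene pair.

    ``n = x1 + x2 = 0`` returns 1 by convention: such a gene carries no
    information and contributes "no rejection" to any empirical rate.
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be non-negative")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly inside (0, 1)")
    return float(_pvalues(x1, x1 + x2, p0))


@dataclass
class TestResult:
    """Per-gene p-values from :func:`test_all`."""

    pvalues: np.ndarray
    c_used: float
    n_vec: np.ndarray

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        self.n_vec = np.asarray(self.n_vec)


def test_all(table, c: float, n1: int | None = None, n2: int | None = None) -> TestResult:
    """Exact test for every ortholog pair of a table at scaling factor ``c``.

    Depths default to the table's own column sums; explicit ``n1``/``n2``
    allow testing a subset of genes (for instance the conserved anchor set)
    against the depths of the full table.
    """
    if c <= 0:
        raise ValueError("scaling factor c must be > 0")
    df = table.data
    N1 = table.n1 if n1 is None else int(n1)
    N2 = table.n2 if n2 is None else int(n2)
    x1 = df["x1"].to_numpy(dtype=float)
    x2 = df["x2"].to_numpy(dtype=float)
    p0 = null_probability(
        df["L1"].to_numpy(dtype=float), df["L2"].to_numpy(dtype=float), N1, N2, c
    )
    n = x1 + x2
    return TestResult(pvalues=_pvalues(x1, n, p0), c_used=float(c), n_vec=n)


def write_test_results(
    result: TestResult,
    table,
    path: str | Path,
    alpha: float | None = None,
    extra_comments: Sequence[str] = (),
) -> None:
    """Write per-gene results as delimited text with a '#' provenance header."""
    df = table.data[["gene_id", "x1", "x2", "L1", "L2"]].copy()
    df["p_value"] = result.pvalues
    with open(Path(path), "w") as fh:
        fh.write(f"# scaling factor c = {result.c_used!r}\n")
        if alpha is not None:
            fh.write(f"# alpha = {alpha!r}\n")
        for line in extra_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
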