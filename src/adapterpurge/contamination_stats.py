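"""Poisson enrichment model for adapter contamination.

The null model assumes equal base probabilities and independence among
sites, so a fixed 12-mer occurs at any given window start with probability
1/4^12. For an assembly of total length X with y contigs there are
X − 11y window starts (the last 11 bases of each contig cannot start a
12-mer), giving the expected chance count

    lambda = (X − 11 y) / 4^12.

The enrichment p-value for observing k or more adapters is the Poisson
upper tail

    Pr(O >= k) = 1 − exp(−lambda) * sum_{j=0}^{k−1} lambda^j / j!

evaluated through the regularized lower incomplete gamma function, which
stays accurate deep in the tail (the significance thresholds of interest
reach 1e-16, far beyond where naive summation underflows). Multiple
assemblies are corrected with Benjamini–Hochberg FDR, and the relationship
between adapter counts and post-repair contig merges is modelled with a
Poisson GLM (log link).

Orientation convention: lambda as defined above is for a single 12-mer,
while observed counts k conventionally include both the adapter and its
reverse complement. The default keeps that pairing (reproducing published
database screens); set ``lambda_both_strands=True`` for a strand-symmetric
null that doubles lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.special as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .fasta_io import AssemblyStats

__all__ = [
    "PVALUE_FLOOR",
    "ContaminationTest",
    "GlmFit",
    "expected_adapter_count",
    "enrichment_pvalue",
    "build_test",
    "fdr_correct",
    "expected_false_positives",
    "poisson_glm",
]

#: Smallest p-value stored; smaller values are clamped (reported as
#: "< 1e-300" in text output). Keeps results representable in double
#: precision well below the 1e-16 significance threshold.
PVALUE_FLOOR = 1e-300


@dataclass(frozen=True)
class ContaminationTest:
    """One assembly's enrichment test: lambda, observed k, p, q."""

    assembly_name: str
    lambda_: float
    k_observed: int
    p_value: float
    q_value: float | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class GlmFit:
    """Poisson-GLM fit of merge counts on adapter counts (log link)."""

    slope: float
    intercept: float
    slope_p_value: float


def expected_adapter_count(
    stats: AssemblyStats,
    adapter_len: int = 12,
    both_strands: bool = False,
) -> float:
    """Expected chance adapter count lambda for one assembly.

    (X − (L−1)·y) / 4^L for adapter length L; for L=12 this is exactly the
    12-mer null expectation. ``both_strands`` doubles the expectation for
    a null covering the adapter and its reverse complement jointly.
    """
    if adapter_len < 1:
        raise ValueError("adapter_len must be >= 1")
    X = stats.total_length_X
    y = stats.contig_count_y
    windows = X - (adapter_len - 1) * y
    if windows <= 0:
        raise ValueError(
            f"assembly shorter than adapter: X={X}, y={y} leave no "
            f"{adapter_len}-base window"
        )
    lam = windows / 4.0**adapter_len
    return 2.0 * lam if both_strands else lam


def enrichment_pvalue(lambda_: float, k: int) -> float:
    """Poisson upper-tail probability Pr(O >= k) under expectation lambda.

    Computed as the regularized lower incomplete gamma function P(k, lambda)
    (identical to the Poisson survival function at k−1), which remains
    accurate for lambda as small as 1e-12 and k up to 1e4. Results below
    :data:`PVALUE_FLOOR` are clamped to it. k = 0 returns exactly 1.
    """
    if lambda_ <= 0:
        raise ValueError(f"lambda must be positive, got {lambda_}")
    if k < 0 or int(k) != k:
        raise ValueError(f"k must be a nonnegative integer, got {k}")
    if k == 0:
        return 1.0
    p = float(sps.gammainc(k, lambda_))
    if p < PVALUE_FLOOR:
        return PVALUE_FLOOR
    return min(p, 1.0)


def build_test(
    assembly_name: str,
    stats: AssemblyStats,
    k_observed: int,
    adapter_len: int = 12,
    lambda_both_strands: bool = False,
) -> ContaminationTest:
    """Convenience constructor: lambda and p-value for one assembly."""
    lam = expected_adapter_count(
        stats, adapter_len=adapter_len, both_strands=lambda_both_strands
    )
    return ContaminationTest(
        assembly_name=assembly_name,
        lambda_=lam,
        k_observed=int(k_observed),
        p_value=enrichment_pvalue(lam, int(k_observed)),
    )


def fdr_correct(tests, fdr: float = 0.1) -> list[ContaminationTest]:
    """Benjamini–Hochberg step-up q-values across a batch of tests.

    Returns new records with ``q_value`` filled and ``significant`` set
    where q <= fdr. Order of the input collection is preserved.
    """
    tests = list(tests)
    if not tests:
        raise ValueError("fdr_correct needs at least one test")
    if not (0 < fdr <= 1):
        raise ValueError(f"fdr must be in (0, 1], got {fdr}")
    pvals = np.array([t.p_value for t in tests])
    _, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return [
        replace(t, q_value=float(q), significant=bool(q <= fdr))
        for t, q in zip(tests, qvals)
    ]


def expected_false_positives(n_tests: int, alpha: float) -> float:
    """Expected count of chance-significant assemblies at threshold alpha."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return n_tests * alpha


def poisson_glm(x, yresp, maxiter: int = 100) -> GlmFit:
    """Poisson regression (log link) of merge counts on adapter counts.

    Fit by iteratively reweighted least squares; the slope p-value is the
    Wald test on the adapter-count coefficient.
    """
    x = np.asarray(x, dtype=float)
    yresp = np.asarray(yresp, dtype=float)
    if x.shape != yresp.shape or x.ndim != 1:
        raise ValueError("x and yresp must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.any(x < 0) or np.any(yresp < 0):
        raise ValueError("counts must be nonnegative")
    if np.unique(x).size < 2:
        raise ValueError("x has a single distinct value; slope not identifiable")
    if not np.any(yresp > 0):
        raise ValueError("all-zero response; Poisson GLM not identifiable")
    design = sm.add_constant(x)
    model = sm.GLM(yresp, design, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter)
    if not res.converged:
        raise RuntimeError(f"Poisson GLM did not converge in {maxiter} iterations")
    return GlmFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_p_value=float(res.pvalues[1]),
    )
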