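"""Assessment of evolutionary potential.

Two population-level measures: **mean fitness** (arithmetic mean of
merit/gestation over living organisms, reported in log2 because
metabolic rewards are base-2 exponential) and **task success**

    S_p = (1 / N_p) * sum_i sum_t q_{i,t}

the per-organism task qualities q in [0, 1] summed over organisms i and
tasks t and divided by the population size N_p; its maximum is the task
count T of the environment, and the normalized form divides by T.

Replicate populations of two architectures are compared with the
Wilcoxon rank-sum test under sequential-Bonferroni (Holm) correction
across the comparison family, with non-parametric bootstrap confidence
intervals (2.5% / 97.5% quantiles, 10,000 iterations) on the medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .isa import ArchitectureSpec

__all__ = [
    "PopulationSample", "task_success", "normalized_task_success",
    "mean_fitness_log2", "bootstrap_ci", "compare_groups",
    "ComparisonResult", "multinop_usage", "MultinopUsage",
    "dominant_genotype",
]


@dataclass
class PopulationSample:
    """Per-organism fitness values and the N_p x T task-quality matrix
    of one population at the end of a run."""

    fitness_values: list
    quality_matrix: np.ndarray

    def __post_init__(self):
        self.quality_matrix = np.asarray(self.quality_matrix, dtype=float)
        if self.quality_matrix.ndim != 2:
            raise ValueError("quality matrix must be 2-dimensional")
        q = self.quality_matrix
        if q.size and (q.min() < 0.0 or q.max() > 1.0):
            raise ValueError("task qualities must lie in [0, 1]")


def task_success(sample: PopulationSample) -> float:
    """S_p: summed task qualities per organism, averaged over the
    population."""
    n = sample.quality_matrix.shape[0]
    if n == 0:
        raise ValueError("task success is undefined for an empty population")
    return float(sample.quality_matrix.sum() / n)


def normalized_task_success(s_p: float, n_tasks: int) -> float:
    return s_p / n_tasks


def mean_fitness_log2(sample_or_values) -> float:
    """log2 of the arithmetic mean fitness of the living population."""
    values = getattr(sample_or_values, "fitness_values", sample_or_values)
    if len(values) == 0:
        raise ValueError("no fitness values (no organism has divided)")
    return float(np.log2(np.mean(values)))


def bootstrap_ci(values: Sequence[float], iterations: int = 10_000,
                 quantiles=(2.5, 97.5),
                 statistic: Callable = np.median, rng=None):
    """Non-parametric bootstrap quantile interval of a statistic."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap requires at least two values")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, values.size, size=(iterations, values.size))
    boot = statistic(values[idx], axis=1)
    lo, hi = np.percentile(boot, quantiles)
    return float(lo), float(hi)


@dataclass
class ComparisonResult:
    labels: list
    medians_reference: list
    medians_treatment: list
    ci_reference: list
    ci_treatment: list
    p_values: list
    p_adjusted: list
    significant: list
    alpha: float


def compare_groups(comparisons, alpha: float = 0.05,
                   bootstrap_iterations: int = 10_000,
                   rng=None) -> ComparisonResult:
    """Rank-sum comparisons of treatment vs reference replicate values.

    ``comparisons`` is a list of ``(label, reference_values,
    treatment_values)`` triples forming one correction family.  P-values
    come from the two-sided Wilcoxon rank-sum test (midranks on ties;
    exact null distribution for small untied samples) and are adjusted
    by Holm's step-down procedure — the standard reading of "sequential
    Bonferroni".
    """
    rng = np.random.default_rng(rng)
    labels, med_r, med_t, ci_r, ci_t, pvals = [], [], [], [], [], []
    for label, ref, treat in comparisons:
        ref = np.asarray(ref, dtype=float)
        treat = np.asarray(treat, dtype=float)
        if ref.size < 2 or treat.size < 2:
            raise ValueError(f"{label}: both groups need >= 2 values")
        labels.append(label)
        med_r.append(float(np.median(ref)))
        med_t.append(float(np.median(treat)))
        ci_r.append(bootstrap_ci(ref, bootstrap_iterations, rng=rng))
        ci_t.append(bootstrap_ci(treat, bootstrap_iterations, rng=rng))
        p = sps.mannwhitneyu(treat, ref, alternative="two-sided",
                             method="auto").pvalue
        pvals.append(float(p))
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return ComparisonResult(
        labels=labels, medians_reference=med_r, medians_treatment=med_t,
        ci_reference=ci_r, ci_treatment=ci_t, p_values=pvals,
        p_adjusted=[float(p) for p in p_adj],
        significant=[bool(r) for r in reject], alpha=alpha)


@dataclass
class MultinopUsage:
    fraction: float        # NaN when no candidate instructions exist
    n_candidates: int      # instructions that may take more than one nop
    n_multi_used: int      # of those, followed by >= 2 nops


def multinop_usage(genome: Sequence[int], arch: ArchitectureSpec,
                   ) -> MultinopUsage:
    """Fraction of multi-argument instructions actually using more than
    one nop modifier in a genome (fully associative architectures)."""
    from .vcpu import compile_architecture
    ca = compile_architecture(arch)
    L = len(genome)
    n_cand = n_used = 0
    for pos, op in enumerate(genome):
        if ca.maxnops[op] < 2:
            continue
        n_cand += 1
        run = 0
        for k in range(1, L):
            if ca.nop_idx[genome[(pos + k) % L]] < 0:
                break
            run += 1
            if run >= 2:
                break
        if run >= 2:
            n_used += 1
    frac = n_used / n_cand if n_cand else float("nan")
    return MultinopUsage(frac, n_cand, n_used)


def dominant_genotype(genomes: Sequence[Sequence[int]]) -> list:
    """Most abundant genome sequence; ties break to earliest seen."""
    counts = {}
    order = {}
    for i, g in enumerate(genomes):
        key = tuple(g)
        counts[key] = counts.get(key, 0) + 1
        order.setdefault(key, i)
    if not counts:
        raise ValueError("empty population")
    best = max(counts, key=lambda k: (counts[k], -order[k]))
    return list(best)
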