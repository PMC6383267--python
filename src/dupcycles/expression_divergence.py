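"""Expression divergence between duplicate gene copies.

For every duplicate pair whose two copies are both expressed in at least
one sample, the Pearson correlation r of their log10(TPM + 1) expression
profiles is compared against an empirical null: the distribution of r over
random gene pairs drawn from expressed genes.  The cutoff is the quantile
of the null chosen so that 95% (by default) of random pairs fall below it;
pairs with r below the cutoff are called *diverged*, the rest *conserved*.

"Expressed" means TPM above a threshold; the threshold is the mean over
samples of the per-sample median TPM of intergenic sequences when an
intergenic TPM matrix is available (their medians are close to zero), and
1.0 TPM otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .dup_classifier import DuplicatePair, Mode
from .genome_io import TpmMatrix

DEFAULT_TPM_THRESHOLD = 1.0


@dataclass(frozen=True)
class DivergenceCall:
    pair_id: str
    gene_a: str
    gene_b: str
    mode: str
    pearson_r: float | None
    status: str  # "conserved", "diverged", or "not_analyzed"
    cutoff_used: float
    reason: str | None = None


def derive_expression_threshold(intergenic_tpm: TpmMatrix) -> float:
    """Mean over samples of the per-sample median intergenic TPM."""
    values = intergenic_tpm.values
    if values.size == 0:
        raise ValueError("intergenic TPM matrix is empty")
    return float(np.mean(np.median(values, axis=0)))


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between two (n, m) arrays.

    Rows with a constant profile get NaN (r is undefined there), including
    when mean-subtraction would only leave rounding dust.
    """
    constant = (np.ptp(a, axis=1) == 0) | (np.ptp(b, axis=1) == 0)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / denom
    r[constant] = np.nan
    return r


def random_pair_cutoff(
    log_expr: np.ndarray,
    expressed_idx: np.ndarray,
    exclude: set[frozenset[int]],
    n_random: int = 10000,
    quantile: float = 0.95,
    seed: int | None = None,
) -> float:
    """Empirical null cutoff: the ``quantile`` of r over random gene pairs.

    Pairs are drawn uniformly (distinct pairs, both genes expressed, not in
    ``exclude``); pairs whose r is undefined (a constant profile) are
    redrawn.  Raises when not enough distinct pairs exist.
    """
    rng = np.random.default_rng(seed)
    n_genes = expressed_idx.size
    max_pairs = n_genes * (n_genes - 1) // 2 - len(exclude)
    if max_pairs < n_random:
        raise ValueError(
            f"cannot draw {n_random} distinct random pairs from {n_genes} "
            "expressed genes"
        )
    chosen: set[frozenset[int]] = set()
    r_values: list[float] = []
    while len(r_values) < n_random:
        need = n_random - len(r_values)
        ii = expressed_idx[rng.integers(0, n_genes, size=2 * need + 16)]
        jj = expressed_idx[rng.integers(0, n_genes, size=2 * need + 16)]
        for i, j in zip(ii, jj):
            if i == j:
                continue
            key = frozenset((int(i), int(j)))
            if key in chosen or key in exclude:
                continue
            r = _pearson_rows(log_expr[None, i], log_expr[None, j])[0]
            if not np.isfinite(r):
                continue
            chosen.add(key)
            r_values.append(float(r))
            if len(r_values) == n_random:
                break
    return float(np.quantile(r_values, quantile))


def call_divergence(
    pairs: Iterable[DuplicatePair],
    tpm: TpmMatrix,
    threshold: float = DEFAULT_TPM_THRESHOLD,
    n_random: int = 10000,
    quantile: float = 0.95,
    seed: int | None = None,
) -> tuple[list[DivergenceCall], float]:
    """Call conserved/diverged expression for duplicate pairs.

    Returns the calls plus the null cutoff used.  Pairs with a copy absent
    from the matrix, never expressed above ``threshold``, or with a
    zero-variance profile are labelled ``not_analyzed``.
    """
    pairs = list(pairs)
    if len(tpm.sample_ids) < 3:
        raise ValueError("Pearson correlation needs at least 3 samples")
    gene_index = {g: i for i, g in enumerate(tpm.gene_ids)}
    log_expr = tpm.log10p().to_numpy()
    expressed_mask = (tpm.values > threshold).any(axis=1)
    expressed_idx = np.flatnonzero(expressed_mask)

    exclude: set[frozenset[int]] = set()
    for p in pairs:
        ia, ib = gene_index.get(p.gene_a), gene_index.get(p.gene_b)
        if ia is not None and ib is not None:
            exclude.add(frozenset((ia, ib)))

    cutoff = random_pair_cutoff(
        log_expr, expressed_idx, exclude, n_random=n_random, quantile=quantile,
        seed=seed,
    )

    calls: list[DivergenceCall] = []
    for p in pairs:
        pair_id = f"{p.gene_a}|{p.gene_b}"
        mode = str(p.mode)
        ia, ib = gene_index.get(p.gene_a), gene_index.get(p.gene_b)
        if ia is None or ib is None:
            calls.append(DivergenceCall(pair_id, p.gene_a, p.gene_b, mode, None,
                                        "not_analyzed", cutoff, "gene not in matrix"))
            continue
        if not (expressed_mask[ia] and expressed_mask[ib]):
            calls.append(DivergenceCall(pair_id, p.gene_a, p.gene_b, mode, None,
                                        "not_analyzed", cutoff, "not expressed"))
            continue
        r = _pearson_rows(log_expr[None, ia], log_expr[None, ib])[0]
        if not np.isfinite(r):
            calls.append(DivergenceCall(pair_id, p.gene_a, p.gene_b, mode, None,
                                        "not_analyzed", cutoff, "zero variance"))
            continue
        status = "diverged" if r < cutoff else "conserved"
        calls.append(
            DivergenceCall(pair_id, p.gene_a, p.gene_b, mode, float(r), status, cutoff)
        )
    return calls, cutoff


def compare_proportions(
    diverged_a: int, total_a: int, diverged_b: int, total_b: int
) -> tuple[float, float]:
    """Two-sided Fisher's exact test on diverged/total counts of two groups."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if diverged_a > total_a or diverged_b > total_b:
        raise ValueError("diverged count exceeds total")
    if diverged_a < 0 or diverged_b < 0:
        raise ValueError("counts must be non-negative")
    table = [
        [diverged_a, total_a - diverged_a],
        [diverged_b, total_b - diverged_b],
    ]
    odds_ratio, p_value = stats.fisher_exact(table, alternative="two-sided")
    return float(odds_ratio), float(p_value)


def divergence_summary(calls: Sequence[DivergenceCall]) -> dict[str, dict[str, int]]:
    """Per-mode counts of conserved / diverged / not_analyzed calls."""
    out: dict[str, dict[str, int]] = {}
    for call in calls:
        bucket = out.setdefault(
            call.mode, {"conserved": 0, "diverged": 0, "not_analyzed": 0}
        )
        bucket[call.status] += 1
    return out
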