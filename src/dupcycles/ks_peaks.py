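"""Ks age distributions: block means, Gaussian mixture fitting, trend fits.

The age distribution used for peak calling is the distribution of *mean
anchor Ks per collinear block* (one value per block, saturated anchors
excluded).  A one-dimensional Gaussian mixture is fitted by EM for each
candidate component count k; the model minimising

    BIC = -2 log L + (3k - 1) ln n

is selected.  Component means locate WGD (or, for inter-genome blocks,
speciation) peaks; the most recent event is the smallest mean among
components with non-negligible weight.

Initialisation places component means at spread quantiles of the data with
seeded random perturbation, restarted ``n_init`` times; standard deviations
are floored at ``sd_floor`` to prevent the classic degenerate-spike EM
solution on discretised Ks values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .codon_evol import KaKsResult
from .collinearity import CollinearBlock


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: float
    sd: float


@dataclass(frozen=True)
class KsMixtureModel:
    k: int
    components: tuple[MixtureComponent, ...]
    log_likelihood: float
    bic: float
    n_points: int
    bic_table: tuple[tuple[int, float], ...] = ()

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for c in self.components:
            out += c.weight * stats.norm.pdf(x, c.mean, c.sd)
        return out


@dataclass(frozen=True)
class TrendFit:
    model: str  # "linear" or "exponential"
    a: float
    b: float
    pearson_r: float
    p_value: float
    chi_square: float


def _ks_value(entry) -> float | None:
    """Extract a usable Ks from a KaKsResult or a bare float."""
    if entry is None:
        return None
    if isinstance(entry, KaKsResult):
        if entry.ks is None or entry.excluded:
            return None
        return entry.ks
    value = float(entry)
    return value if math.isfinite(value) else None


def block_mean_ks(
    blocks: Sequence[CollinearBlock],
    kaks_table: Mapping[frozenset[str], "KaKsResult | float"],
    ks_max: float = 5.0,
) -> list[float]:
    """Mean usable anchor Ks per block; blocks with no usable anchor dropped.

    ``kaks_table`` maps unordered gene pairs to KaKsResult objects or bare
    Ks floats.  Anchors with undefined Ks or Ks > ks_max are excluded.
    """
    means: list[float] = []
    for block in blocks:
        values = []
        for gene_a, gene_b in block.gene_pairs():
            ks = _ks_value(kaks_table.get(frozenset((gene_a, gene_b))))
            if ks is not None and ks <= ks_max:
                values.append(ks)
        if values:
            means.append(float(np.mean(values)))
        else:
            import warnings

            warnings.warn(
                f"block {block.chrom_a}&{block.chrom_b} has no usable anchor Ks; dropped"
            )
    return means


def _em_fit(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_init: int,
    tol: float,
    max_iter: int,
    sd_floor: float,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Best-of-n_init EM fit for fixed k. Returns (loglik, w, mu, sd).

    All restarts are iterated together as one (n_init, n, k) batch; each
    restart stops updating once its log-likelihood gain drops below tol.
    """
    n = x.size
    spread = max(float(np.std(x)), sd_floor)
    quantile_means = np.quantile(x, (np.arange(k) + 0.5) / k)
    mu = np.tile(quantile_means, (n_init, 1))
    if n_init > 1:
        mu[1:] += rng.normal(0.0, spread / (2 * k), (n_init - 1, k))
    sd = np.full((n_init, k), max(spread / max(k, 1), sd_floor))
    w = np.full((n_init, k), 1.0 / k)
    prev_ll = np.full(n_init, -np.inf)
    active = np.arange(n_init)
    log_2pi = 0.5 * math.log(2 * math.pi)
    for _ in range(max_iter):
        # (active inits, k, n) layout keeps the long axis contiguous
        inv_sd = 1.0 / sd[active]
        z = (x[None, None, :] - mu[active, :, None]) * inv_sd[:, :, None]
        pdf = (w[active] * inv_sd)[:, :, None] * np.exp(-0.5 * z * z)
        norm = np.maximum(pdf.sum(axis=1), 1e-300)  # (I, n)
        ll = np.log(norm).sum(axis=1) - n * log_2pi
        # EM guarantees monotone likelihood; a violation indicates a bug
        assert np.all(ll >= prev_ll[active] - 1e-8), "EM log-likelihood decreased"
        gain = ll - prev_ll[active]
        prev_ll[active] = ll
        keep = gain >= tol
        if not keep.any():
            break
        resp = pdf[keep] / norm[keep][:, None, :]
        active = active[keep]
        nk = np.maximum(resp.sum(axis=2), 1e-12)
        w[active] = nk / n
        mu[active] = (resp * x[None, None, :]).sum(axis=2) / nk
        var = (resp * (x[None, None, :] - mu[active, :, None]) ** 2).sum(axis=2) / nk
        sd[active] = np.maximum(np.sqrt(var), sd_floor)
    best = int(np.argmax(prev_ll))
    return float(prev_ll[best]), w[best].copy(), mu[best].copy(), sd[best].copy()


def fit_gmm(
    values: Iterable[float],
    k_range: Sequence[int] = (1, 2, 3, 4, 5),
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    sd_floor: float = 0.01,
) -> KsMixtureModel:
    """Fit 1-D Gaussian mixtures by EM and select k by minimal BIC."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 20:
        raise ValueError(
            f"only {x.size} values; peak calling on fewer than 20 points is "
            "unreliable, refusing to fit"
        )
    rng = np.random.default_rng(seed)
    table: list[tuple[int, float]] = []
    best: tuple[float, KsMixtureModel] | None = None
    for k in k_range:
        ll, w, mu, sd = _em_fit(x, k, rng, n_init, tol, max_iter, sd_floor)
        bic = -2.0 * ll + (3 * k - 1) * math.log(x.size)
        order = np.argsort(mu)
        components = tuple(
            MixtureComponent(float(w[i]), float(mu[i]), float(sd[i])) for i in order
        )
        model = KsMixtureModel(k, components, ll, bic, x.size)
        table.append((k, bic))
        if best is None or bic < best[0]:
            best = (bic, model)
    assert best is not None
    chosen = best[1]
    return KsMixtureModel(
        chosen.k,
        chosen.components,
        chosen.log_likelihood,
        chosen.bic,
        chosen.n_points,
        tuple(table),
    )


def select_recent_peak(model: KsMixtureModel, min_weight: float = 0.05) -> float:
    """Smallest component mean among components with weight >= min_weight."""
    eligible = [c.mean for c in model.components if c.weight >= min_weight]
    if not eligible:
        raise ValueError(
            f"no mixture component reaches weight {min_weight}; cannot pick a peak"
        )
    return min(eligible)


def fit_decay(
    x: Sequence[float], y: Sequence[float], model: str = "exponential"
) -> TrendFit:
    """Fit duplicate-pair abundance against peak age.

    ``model="linear"`` fits y = a + b x by least squares; ``"exponential"``
    fits y = a exp(b x), initialised from the log-linear fit.  Both report
    the Pearson correlation of (x, y) with its two-sided p-value, and the
    chi-square goodness of fit sum((obs - fit)^2 / fit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a trend fit")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant x or y: correlation undefined")
    r, p = stats.pearsonr(x, y)
    if model == "linear":
        fit = stats.linregress(x, y)
        a, b = float(fit.intercept), float(fit.slope)
        fitted = a + b * x
    elif model == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential fit requires positive y values")
        log_fit = stats.linregress(x, np.log(y))
        p0 = (math.exp(log_fit.intercept), log_fit.slope)
        (a, b), _ = optimize.curve_fit(
            lambda t, a_, b_: a_ * np.exp(b_ * t), x, y, p0=p0, maxfev=10000
        )
        a, b = float(a), float(b)
        fitted = a * np.exp(b * x)
    else:
        raise ValueError(f"unknown trend model: {model}")
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.sum((y - fitted) ** 2 / np.where(fitted != 0, fitted, np.nan)))
    return TrendFit(model, a, b, float(r), float(p), chi2)
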