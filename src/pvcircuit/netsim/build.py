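"""Construction of the structured E/I weight matrix.

Connection strength from source neuron i to target j is modulated by a
product of circular kernels phi(gamma_i, gamma_j, kappa) = exp(kappa *
cos(gamma_i - gamma_j)) over the tuning dimensions, normalized per source
neuron to a probability density over its targets within each class block
(subtract the minimum, divide by the sum).  A specificity parameter per
class determines the proportion of each neuron's output weight distributed
by this density versus uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import NetworkConfig

logger = logging.getLogger(__name__)

__all__ = ["phi", "assign_preferences", "specificity_block", "build_weights",
           "NetworkModel", "build_network"]


def phi(gamma_i, gamma_j, kappa: float) -> np.ndarray:
    """Circular tuning kernel exp(kappa * cos(gamma_i - gamma_j)).

    Symmetric and 2*pi periodic in both arguments; kappa = 0 gives 1.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    return np.exp(kappa * np.cos(np.asarray(gamma_i, float) - np.asarray(gamma_j, float)))


def assign_preferences(config: NetworkConfig, seed=None) -> np.ndarray:
    """Per-neuron preferred tuning values, i.i.d. uniform over [-pi, pi).

    Returns an (N, D) array.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed if seed is None else seed))
    return rng.uniform(-np.pi, np.pi, size=(config.n, config.d))


def specificity_block(
    prefs_src: np.ndarray,
    prefs_dst: np.ndarray,
    kappa: float,
    negative: bool = False,
    exclude_diag: bool = False,
) -> np.ndarray:
    """Normalized specificity block S_BA, shape (n_dst, n_src).

    Entry (j, i) starts from prod_d phi(gamma_i^d, gamma_j^d, kappa) (or one
    minus that product for the ``negative`` lateral-inhibition variant), then
    each source column is normalized over its targets: subtract the column
    minimum and divide by the column sum, yielding min 0 and sum 1.  With
    ``exclude_diag`` (same-class blocks) the self entry is removed before
    normalization and fixed at 0.  Degenerate constant columns fall back to
    a uniform density (logged) since the normalization would divide by zero.
    """
    src = np.atleast_2d(np.asarray(prefs_src, float))
    dst = np.atleast_2d(np.asarray(prefs_dst, float))
    n_src, n_dst = src.shape[0], dst.shape[0]
    log_raw = np.zeros((n_dst, n_src))
    for d in range(src.shape[1]):
        log_raw += kappa * np.cos(dst[:, d][:, None] - src[:, d][None, :])
    raw = np.exp(log_raw)
    if negative:
        raw = 1.0 - raw

    if exclude_diag:
        if n_src != n_dst:
            raise ValueError("exclude_diag requires a square block")
        np.fill_diagonal(raw, np.nan)

    with np.errstate(invalid="ignore"):
        cmin = np.nanmin(raw, axis=0)
        shifted = raw - cmin
        csum = np.nansum(shifted, axis=0)
    out = np.empty_like(raw)
    good = csum > 0
    if np.any(~good):
        logger.info("uniform fallback for %d constant source column(s)",
                    int(np.sum(~good)))
    n_targets = n_dst - 1 if exclude_diag else n_dst
    out[:, good] = shifted[:, good] / csum[good]
    out[:, ~good] = 1.0 / n_targets
    if exclude_diag:
        np.fill_diagonal(out, 0.0)
    return out


def build_weights(config: NetworkConfig, prefs: np.ndarray) -> np.ndarray:
    """Signed (N, N) weight matrix W[target, source]; E columns first.

    Block form: W_EE = w_E [f_E |s_E| S_EE + (1-|s_E|)/N] and companions,
    with E->I scaled by d_IE and inhibitory source columns negated.  When
    s_I < 0 the output blocks of inhibitory neurons use the reversed
    (lateral) kernel.  Self-connections are excluded; the uniform weight a
    neuron would place on itself is redistributed over its same-class
    targets so each column sum is preserved exactly.
    """
    n, n_e = config.n, config.n_e
    pe, pi = prefs[:n_e], prefs[n_e:]
    se, si = abs(config.s_e), abs(config.s_i)
    neg = config.s_i < 0

    s_ee = specificity_block(pe, pe, config.k_ee, exclude_diag=True)
    s_ie = specificity_block(pe, pi, config.k_ie)             # E -> I
    s_ei = specificity_block(pi, pe, config.k_ei, negative=neg)  # I -> E
    s_ii = specificity_block(pi, pi, config.k_ii, negative=neg, exclude_diag=True)

    def uniform(n_targets_in_block, same_class):
        # per-entry uniform weight preserving the column sum with a zero diagonal
        if same_class:
            return np.where(np.eye(n_targets_in_block, dtype=bool), 0.0,
                            n_targets_in_block / (n * (n_targets_in_block - 1)))
        return None  # cross blocks use the scalar 1/n

    w = np.empty((n, n))
    u_ee = uniform(n_e, True)
    u_ii = uniform(config.n_i, True)
    w[:n_e, :n_e] = config.w_e * (config.f_e * se * s_ee + (1 - se) * u_ee)
    w[n_e:, :n_e] = config.w_e * config.d_ie * (
        config.f_i * si * s_ie + (1 - si) / n)
    w[:n_e, n_e:] = -config.w_i * (config.f_e * si * s_ei + (1 - si) / n)
    w[n_e:, n_e:] = -config.w_i * (config.f_i * si * s_ii + (1 - si) * u_ii)
    return w


@dataclass
class NetworkModel:
    config: NetworkConfig
    prefs: np.ndarray   # (N, D)
    weights: np.ndarray  # signed (N, N), W[target, source]

    @property
    def n_e(self) -> int:
        return self.config.n_e

    @property
    def is_excitatory(self) -> np.ndarray:
        m = np.zeros(self.config.n, bool)
        m[: self.n_e] = True
        return m


def build_network(config: NetworkConfig, seed=None) -> NetworkModel:
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed if seed is None else seed))
    prefs = assign_preferences(config, rng)
    return NetworkModel(config, prefs, build_weights(config, prefs))
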