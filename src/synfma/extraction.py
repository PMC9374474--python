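"""Non-negative matrix factorisation of EMG envelopes and model-order choice.

The envelope matrix ``E`` (frames x muscles) is factorised as
``E ~ H.T-free form: E.T ~ W @ H`` with ``W`` (muscles x K) the spatial
synergies and ``H`` (K x frames) the temporal coefficients, both
non-negative.  The number of synergies is the smallest K whose variance
accounted for (VAF) exceeds a threshold (default 0.8):

    VAF = 1 - ||E - (W H).T||_F^2 / ||E||_F^2        (uncentred)

Factorisation uses multiplicative updates for the Frobenius objective with
several random restarts; the best restart by VAF wins, ties broken by the
lowest restart index so a seed fully determines the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import SynergyDecomposition, ValidationError

_EPS = 1e-12


class VAFDomainError(ValueError):
    """VAF is undefined (all-zero envelope)."""


class ModelOrderError(RuntimeError):
    """No synergy count up to k_max reaches the VAF threshold."""

    def __init__(self, msg: str, best_vaf: float, vaf_curve: dict[int, float]):
        super().__init__(msg)
        self.best_vaf = best_vaf
        self.vaf_curve = vaf_curve


@dataclass
class ExtractionConfig:
    vaf_threshold: float = 0.8
    k_max: int = 25
    n_restarts: int = 20
    max_iter: int = 1000
    convergence_tol: float = 1e-6   # relative change of the objective
    seed: int = 0

    def validate(self, n_muscles: int | None = None) -> None:
        if not 0 < self.vaf_threshold <= 1:
            raise ValidationError("vaf_threshold must be in (0, 1]")
        if n_muscles is not None and self.k_max > n_muscles:
            raise ValidationError("k_max cannot exceed the number of muscles")


def _as_matrix(E) -> np.ndarray:
    """Accept an EnvelopeMatrix or a plain (frames, muscles) array."""
    values = getattr(E, "values", E)
    return np.asarray(values, dtype=float)


def compute_vaf(E, W: np.ndarray, H: np.ndarray) -> float:
    """Uncentred variance accounted for of the reconstruction ``(W H).T``.

    Negative values are returned as-is: they signal a fit worse than the
    zero reconstruction and are meaningful for diagnostics.
    """
    Em = _as_matrix(E)
    sst = float(np.sum(Em * Em))
    if sst == 0.0:
        raise VAFDomainError("VAF undefined for an all-zero envelope")
    resid = Em - (W @ H).T
    return 1.0 - float(np.sum(resid * resid)) / sst


def _mu_nmf(V: np.ndarray, K: int, rng: np.random.Generator,
            max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative-update NMF of V (muscles x frames) ~ W @ H."""
    m, n = V.shape
    scale = np.sqrt(V.mean() / max(K, 1)) + _EPS
    W = rng.uniform(0.0, 1.0, size=(m, K)) * scale
    H = rng.uniform(0.0, 1.0, size=(K, n)) * scale
    prev_obj = None
    for it in range(max_iter):
        # H <- H * (W^T V) / (W^T W H)
        WtV = W.T @ V
        H *= WtV / (W.T @ W @ H + _EPS)
        # W <- W * (V H^T) / (W H H^T)
        VHt = V @ H.T
        W *= VHt / (W @ (H @ H.T) + _EPS)
        if it % 10 == 9 or it == max_iter - 1:
            resid = V - W @ H
            obj = float(np.sum(resid * resid))
            if prev_obj is not None and prev_obj - obj <= tol * max(prev_obj, _EPS):
                break
            prev_obj = obj
    return W, H


def _normalize_columns(W: np.ndarray, H: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Rescale W columns to unit norm, folding the scale into H rows."""
    norms = np.linalg.norm(W, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return W / safe, H * norms[:, None]


def nmf_factorize(E, K: int, cfg: ExtractionConfig | None = None
                  ) -> SynergyDecomposition:
    """Best-of-restarts NMF of an envelope at a fixed synergy count K.

    Deterministic given ``cfg.seed``: restart ``i`` draws its initialisation
    from seed ``cfg.seed + i``, and ties in VAF go to the lowest restart
    index.
    """
    cfg = cfg or ExtractionConfig()
    Em = _as_matrix(E)
    if not np.all(np.isfinite(Em)):
        raise ValidationError("envelope contains non-finite entries")
    if np.any(Em < 0):
        raise ValidationError("envelope must be non-negative")
    if K < 1:
        raise ValidationError("K must be >= 1")
    V = Em.T  # muscles x frames
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for i in range(cfg.n_restarts):
        rng = np.random.default_rng(cfg.seed + i)
        W, H = _mu_nmf(V, K, rng, cfg.max_iter, cfg.convergence_tol)
        vaf = compute_vaf(Em, W, H)
        if best is None or vaf > best[0]:
            best = (vaf, W, H)
    vaf, W, H = best
    W, H = _normalize_columns(W, H)
    return SynergyDecomposition(W=W, H=H, K=K, vaf=vaf)


def select_synergy_number(E, cfg: ExtractionConfig | None = None
                          ) -> SynergyDecomposition:
    """Smallest K in 1..k_max whose best-of-restarts VAF exceeds the threshold.

    The K -> VAF curve for every K that was evaluated is recorded on the
    returned decomposition.  Raises :class:`ModelOrderError`, carrying the
    best attained VAF and the curve, when no K reaches the threshold.
    """
    cfg = cfg or ExtractionConfig()
    Em = _as_matrix(E)
    cfg.validate(n_muscles=Em.shape[1])
    # The rank-K truncated SVD maximises explained variance over all rank-K
    # approximations, so its cumulative share upper-bounds the NMF VAF at K.
    # Ks whose bound already fails the threshold cannot be selected and are
    # skipped without fitting; the selected K is unchanged.
    sv = np.linalg.svd(Em, compute_uv=False)
    sst = float(np.sum(sv**2))
    if sst == 0.0:
        raise VAFDomainError("VAF undefined for an all-zero envelope")
    svd_share = np.cumsum(sv**2) / sst
    k_start = 1
    while (k_start <= min(cfg.k_max, sv.size) - 1
           and svd_share[k_start - 1] <= cfg.vaf_threshold):
        k_start += 1
    curve: dict[int, float] = {}
    for K in range(k_start, cfg.k_max + 1):
        dec = nmf_factorize(Em, K, cfg)
        curve[K] = dec.vaf
        if dec.vaf > cfg.vaf_threshold:
            dec.vaf_curve = curve
            return dec
    best = max(curve.values())
    raise ModelOrderError(
        f"no K <= {cfg.k_max} exceeded VAF threshold {cfg.vaf_threshold} "
        f"(best attained VAF = {best:.4f})",
        best_vaf=best,
        vaf_curve=curve,
    )
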