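"""Synergy merging: representing patient synergies on the standard basis.

Each (unit-norm) patient synergy is decomposed by non-negative least squares
onto the standard synergies.  The merge count of a patient synergy is the
number of standard synergies whose coefficient strictly exceeds the merging
threshold (default 0.1); the trial's merging rate is the mean merge count
over represented synergies (count >= 1).  A merging rate near 1 means a
one-to-one correspondence with the standard set; values above 1 mean single
patient synergies blend several standard synergies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .standard import DomainError, StandardSynergySet, synergy_similarity
from .tasks import ActivationProfile
from .types import SynergyDecomposition, ValidationError, N_TASK_ITEMS


@dataclass
class MergingResult:
    """Per-trial merging statistics against a standard synergy set."""

    coefficients: np.ndarray          # (K patient synergies, S standards)
    reconstruction_cosine: np.ndarray  # (K,)
    merge_counts: np.ndarray          # int (K,)
    merging_rate: float               # mean count over represented synergies; nan if none
    represented: np.ndarray           # bool (K,), count >= 1
    merging_threshold: float


def decompose_patient_synergy(w: np.ndarray, std: StandardSynergySet
                              ) -> tuple[np.ndarray, float]:
    """NNLS coefficients of one patient synergy on the standard basis.

    Returns the non-negative coefficient vector and the cosine between the
    synergy and its reconstruction ``W_std @ c``.
    """
    w = np.asarray(w, dtype=float)
    if np.linalg.norm(w) == 0:
        raise DomainError("cannot decompose a zero synergy vector")
    if w.shape[0] != std.W_std.shape[0]:
        raise ValidationError("synergy length does not match the standard basis")
    c, _ = nnls(std.W_std, w)
    recon = std.W_std @ c
    cosine = 0.0 if np.linalg.norm(recon) == 0 else synergy_similarity(w, recon)
    return c, cosine


def merging_count(c: np.ndarray, merging_threshold: float = 0.1) -> int:
    """Number of standard synergies with coefficient strictly above threshold."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValidationError("merging coefficients must be non-negative")
    return int(np.sum(c > merging_threshold))


def merging_rate(decomposition: SynergyDecomposition, std: StandardSynergySet,
                 merging_threshold: float = 0.1) -> MergingResult:
    """Trial-level merging statistics for one patient decomposition.

    Synergies with merge count 0 are flagged non-represented and excluded
    from the mean; if no synergy is represented the rate is NaN.
    """
    K = decomposition.K
    S = std.n_synergies
    coeffs = np.zeros((K, S))
    cosines = np.zeros(K)
    for k in range(K):
        coeffs[k], cosines[k] = decompose_patient_synergy(
            decomposition.W[:, k], std
        )
    counts = np.array([merging_count(coeffs[k], merging_threshold)
                       for k in range(K)])
    represented = counts >= 1
    rate = float(counts[represented].mean()) if represented.any() else float("nan")
    return MergingResult(
        coefficients=coeffs,
        reconstruction_cosine=cosines,
        merge_counts=counts,
        merging_rate=rate,
        represented=represented,
        merging_threshold=merging_threshold,
    )


def per_task_merging_rate(result: MergingResult, profile: ActivationProfile
                          ) -> np.ndarray:
    """Per-task-item merging rate over the patient synergies active in the item.

    ``profile`` is the activation profile of the *patient's own* synergies
    (their rescaled temporal coefficients).  Items in which no represented
    synergy is active get NaN — too little activity to evaluate.
    """
    if profile.active.shape[0] != result.merge_counts.shape[0]:
        raise ValidationError(
            "activation profile and merging result disagree on synergy count"
        )
    out = np.full(N_TASK_ITEMS, np.nan)
    for t in range(N_TASK_ITEMS):
        mask = profile.active[:, t] & result.represented
        if mask.any():
            out[t] = float(result.merge_counts[mask].mean())
    return out


def ordered_similarity_matrix(std: StandardSynergySet, W_patient: np.ndarray
                              ) -> tuple[np.ndarray, list[int]]:
    """Cosine similarity matrix (S x K) with patient columns sorted for display.

    Columns are stable-sorted by their best-matching standard synergy (row
    of the column maximum), ties broken by descending maximum similarity,
    so a one-to-one patient set renders as a permutation diagonal.
    Returns the reordered matrix and the column order.
    """
    W_patient = np.asarray(W_patient, dtype=float)
    S, K = std.n_synergies, W_patient.shape[1]
    sim = np.empty((S, K))
    for k in range(K):
        for s in range(S):
            sim[s, k] = synergy_similarity(std.W_std[:, s], W_patient[:, k])
    order = sorted(range(K), key=lambda k: (int(np.argmax(sim[:, k])),
                                            -float(np.max(sim[:, k]))))
    return sim[:, order], order
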