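"""Multi-layer resource allocation with sequence similarity (MRAS scoring).

The tripartite network is scored in two bipartite layers.  Layer 1
(disease-target) builds a target-target weight matrix

    W_T[i, j] = k_target(i, j) * sum_l  A_DT[l, i] * A_DT[l, j] / deg(d_l)

where deg(d_l) is disease l's degree in the disease-target network:
targets sharing a disease exchange resource inversely to that disease's
degree, modulated by their sequence-kernel similarity.  Layer 2
(target-ncRNA) builds the analogous ncRNA-ncRNA matrix

    W_R[i, j] = k_rna(i, j) * sum_l  A_TR[l, i] * A_TR[l, j] / deg'(t_l)

with deg'(t_l) the target's degree in the target-ncRNA network.  The
layers combine into the target-by-ncRNA weight

    W_C = W_T @ (A_TR @ W_R)

and the final disease-by-ncRNA score matrix is P = A_DT @ W_C; within a
disease row, a higher score means a more certain association.  Terms
with a zero-degree denominator are skipped (their numerators are zero
anyway); the division is masked so no 0/0 arises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import SequenceRecord, TripartiteNetwork
from .features import build_feature_matrix, standardize_features
from .kernels import KernelMatrix, KernelParams, make_kernel


@dataclass
class ScoreMatrix:
    """Prediction scores P (m x p) plus the combined weight they came from."""

    disease_ids: list[str]
    ncrna_ids: list[str]
    W_C: np.ndarray  # n x p
    P: np.ndarray  # m x p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.disease_ids, columns=self.ncrna_ids)


def _as_array(k: KernelMatrix | np.ndarray) -> np.ndarray:
    return k.values if isinstance(k, KernelMatrix) else np.asarray(k, dtype=float)


def _co_neighbor(adj: np.ndarray, degrees: np.ndarray) -> np.ndarray:
    """sum_l adj[l, i] * adj[l, j] / degrees[l], skipping zero-degree rows."""
    safe = np.where(degrees > 0, degrees, 1.0)
    weighted = adj / safe[:, None]
    weighted[degrees == 0, :] = 0.0
    c = weighted.T @ adj
    return (c + c.T) / 2.0


def layer1_weights(A_DT: np.ndarray, K_target: KernelMatrix | np.ndarray) -> np.ndarray:
    """Target-target weights W_T from the disease-target layer."""
    A_DT = np.asarray(A_DT, dtype=float)
    k = _as_array(K_target)
    if k.shape != (A_DT.shape[1], A_DT.shape[1]):
        raise ValueError(
            f"kernel shape {k.shape} does not match target count {A_DT.shape[1]}"
        )
    return k * _co_neighbor(A_DT, A_DT.sum(axis=1))


def layer2_weights(
    A_TR: np.ndarray,
    K_rna: KernelMatrix | np.ndarray,
    degrees: np.ndarray | None = None,
) -> np.ndarray:
    """ncRNA-ncRNA weights W_R from the target-ncRNA layer.

    ``degrees`` defaults to each target's degree within the target-ncRNA
    network (row sums of ``A_TR``); pass the disease-target column sums
    to use the targets' degree in the other layer instead.
    """
    A_TR = np.asarray(A_TR, dtype=float)
    k = _as_array(K_rna)
    if k.shape != (A_TR.shape[1], A_TR.shape[1]):
        raise ValueError(
            f"kernel shape {k.shape} does not match ncRNA count {A_TR.shape[1]}"
        )
    if degrees is None:
        degrees = A_TR.sum(axis=1)
    degrees = np.asarray(degrees, dtype=float)
    if degrees.shape != (A_TR.shape[0],):
        raise ValueError("degree vector length does not match target count")
    return k * _co_neighbor(A_TR, degrees)


def combine_weights(W_T: np.ndarray, A_TR: np.ndarray, W_R: np.ndarray) -> np.ndarray:
    """Combined target-by-ncRNA weight W_C = W_T @ (A_TR @ W_R)."""
    W_T = np.asarray(W_T, dtype=float)
    A_TR = np.asarray(A_TR, dtype=float)
    W_R = np.asarray(W_R, dtype=float)
    if W_T.shape[1] != A_TR.shape[0] or A_TR.shape[1] != W_R.shape[0]:
        raise ValueError(
            f"non-conformable shapes W_T {W_T.shape}, A_TR {A_TR.shape}, W_R {W_R.shape}"
        )
    return W_T @ (A_TR @ W_R)


def prediction_scores(A_DT: np.ndarray, W_C: np.ndarray) -> np.ndarray:
    """Disease-by-ncRNA score matrix P = A_DT @ W_C."""
    A_DT = np.asarray(A_DT, dtype=float)
    W_C = np.asarray(W_C, dtype=float)
    if A_DT.shape[1] != W_C.shape[0]:
        raise ValueError(
            f"non-conformable shapes A_DT {A_DT.shape}, W_C {W_C.shape}"
        )
    return A_DT @ W_C


def score_network(
    A_DT: np.ndarray,
    A_TR: np.ndarray,
    K_target: KernelMatrix | np.ndarray,
    K_rna: KernelMatrix | np.ndarray,
    layer2_degree: str = "tr_network",
) -> tuple[np.ndarray, np.ndarray]:
    """Full weight/score computation from adjacencies and precomputed kernels.

    Returns ``(W_C, P)``.  Used by cross-validation, where the kernels
    depend only on the sequences and are computed once while the
    adjacency matrices change per fold.
    """
    if layer2_degree == "tr_network":
        degrees = None
    elif layer2_degree == "dt_network":
        degrees = np.asarray(A_DT, dtype=float).sum(axis=0)
    else:
        raise ValueError(f"unknown layer2_degree mode {layer2_degree!r}")
    w_t = layer1_weights(A_DT, K_target)
    w_r = layer2_weights(A_TR, K_rna, degrees=degrees)
    w_c = combine_weights(w_t, A_TR, w_r)
    return w_c, prediction_scores(A_DT, w_c)


def _ordered_records(
    records: Sequence[SequenceRecord], ids: Sequence[str], what: str
) -> list[SequenceRecord]:
    by_id = {r.id: r for r in records}
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise ValueError(f"no sequence provided for {what} {missing[0]!r}")
    return [by_id[i] for i in ids]


def build_standardized_features(
    net: TripartiteNetwork,
    target_seqs: Sequence[SequenceRecord],
    ncrna_seqs: Sequence[SequenceRecord],
    l: int,
    ddof: int = 0,
):
    """Standardized target and ncRNA feature matrices, rows in network order."""
    t_recs = _ordered_records(target_seqs, net.targets, "target")
    r_recs = _ordered_records(ncrna_seqs, net.ncrnas, "ncRNA")
    fm_t = standardize_features(build_feature_matrix(t_recs, l), ddof=ddof)
    fm_r = standardize_features(build_feature_matrix(r_recs, l), ddof=ddof)
    return fm_t, fm_r


def kernel_pair(
    fm_t,
    fm_r,
    sigma1: float,
    sigma2: float,
    kernel: str = "rbf",
    degree: int = 2,
    sigma_assignment: str = "layer",
) -> tuple[KernelMatrix, KernelMatrix]:
    """Target and ncRNA kernels from standardized features.

    ``sigma_assignment="layer"`` gives sigma1 to the target kernel
    (layer 1) and sigma2 to the ncRNA kernel (layer 2); ``"formula"``
    swaps them, pairing sigma1 with the ncRNA kernel.  The two bandwidths
    are tuned on a symmetric grid, so the choice only relabels the axes.
    """
    if sigma_assignment == "layer":
        s_t, s_r = sigma1, sigma2
    elif sigma_assignment == "formula":
        s_t, s_r = sigma2, sigma1
    else:
        raise ValueError(f"unknown sigma_assignment {sigma_assignment!r}")
    k_t = make_kernel(fm_t, KernelParams(kind=kernel, sigma=s_t, degree=degree))
    k_r = make_kernel(fm_r, KernelParams(kind=kernel, sigma=s_r, degree=degree))
    return k_t, k_r


def run_mras(
    net: TripartiteNetwork,
    target_seqs: Sequence[SequenceRecord],
    ncrna_seqs: Sequence[SequenceRecord],
    l: int = 3,
    sigma1: float = 0.5,
    sigma2: float = 0.5,
    kernel: str = "rbf",
    degree: int = 2,
    sigma_assignment: str = "layer",
    layer2_degree: str = "tr_network",
    ddof: int = 0,
) -> ScoreMatrix:
    """End-to-end pipeline: features -> kernels -> layer weights -> scores.

    Every target and ncRNA in the network must have a sequence; a
    missing one raises ``ValueError`` naming the entity.  The result is
    deterministic for fixed inputs.
    """
    fm_t, fm_r = build_standardized_features(net, target_seqs, ncrna_seqs, l, ddof=ddof)
    k_t, k_r = kernel_pair(fm_t, fm_r, sigma1, sigma2, kernel, degree, sigma_assignment)
    w_c, p = score_network(net.A_DT, net.A_TR, k_t, k_r, layer2_degree)
    return ScoreMatrix(list(net.diseases), list(net.ncrnas), w_c, p)


def rank_predictions(scores: ScoreMatrix, top_k: int = 10) -> pd.DataFrame:
    """Per-disease top-k ncRNAs by descending score (ties by ncRNA order)."""
    rows = []
    p = scores.P
    for i, d in enumerate(scores.disease_ids):
        order = np.argsort(-p[i], kind="stable")[:top_k]
        for rank, j in enumerate(order, start=1):
            rows.append((d, rank, scores.ncrna_ids[j], p[i, j]))
    return pd.DataFrame(rows, columns=["disease", "rank", "ncrna", "score"])
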