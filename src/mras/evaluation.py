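"""Link-cut k-fold cross-validation, ROC/AUC, and bandwidth grid search.

Evaluation treats every disease-ncRNA pair as a prediction instance.  A
pair is positive when it is connected through at least one common
target in the full network, i.e. ``(A_DT @ A_TR)[d, r] >= 1``.  Pairs
are split into k folds (stratified by label, so sparse positives spread
evenly); for each fold the connecting target-ncRNA edges of its
positive pairs are cut from the network, the scorer is re-run on the
cut network, and an ROC curve is computed over the fold's pairs only.
AUCs are averaged over folds and over repeated re-randomizations of the
fold assignment.  The bandwidth pair (sigma1, sigma2) is tuned by
exhaustive search over the 9 x 9 grid {0.1, ..., 0.9}^2 with fold
partitions shared across grid points.

Note the grid search selects on test-fold AUC, replicating the
protocol it models; this is optimistic model selection, not an unbiased
generalization estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .core import build_standardized_features, kernel_pair, score_network
from .data_model import SequenceRecord, TripartiteNetwork
from .kernels import SIGMA_GRID, KernelMatrix

logger = logging.getLogger(__name__)

#: Common FPR grid on which per-fold ROC curves are interpolated and averaged.
ROC_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class LabeledPair:
    disease_id: str
    ncrna_id: str
    label: int


@dataclass
class CVConfig:
    """Cross-validation settings.

    ``repeats`` counts fold re-randomizations (each repeat re-partitions
    all pairs); ``cut_links`` enables the link-cut protocol;
    ``cut_mode`` chooses whether only the connecting target-ncRNA edge
    is removed (``"tr_edge"``) or the disease-target edge as well
    (``"both"``).  ``permute_labels`` shuffles the pair labels before
    evaluation — a null control whose expected AUC is 0.5.
    """

    k: int = 5
    repeats: int = 5
    seed: int = 0
    sigma1: float = 0.5
    sigma2: float = 0.5
    l: int = 3
    kernel: str = "rbf"
    degree: int = 2
    cut_links: bool = True
    cut_mode: str = "tr_edge"
    stratified: bool = True
    sigma_assignment: str = "layer"
    layer2_degree: str = "tr_network"
    permute_labels: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("fold count k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class EvaluationReport:
    fold_aucs: list[float]
    mean_auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    skipped_folds: int = 0
    sigma1: float | None = None
    sigma2: float | None = None
    config: dict = field(default_factory=dict)


@dataclass
class GridSearchResult:
    sigma1: float
    sigma2: float
    mean_auc: float
    grid_sigma1: tuple[float, ...]
    grid_sigma2: tuple[float, ...]
    auc_grid: np.ndarray  # |grid_sigma1| x |grid_sigma2|


def association_labels(net: TripartiteNetwork) -> np.ndarray:
    """m x p 0/1 matrix: 1 iff the pair shares at least one target."""
    return ((net.A_DT @ net.A_TR) >= 1).astype(int)


def enumerate_pairs(net: TripartiteNetwork) -> list[LabeledPair]:
    """All m x p disease-ncRNA pairs with their connectivity labels."""
    lab = association_labels(net)
    return [
        LabeledPair(d, r, int(lab[i, j]))
        for i, d in enumerate(net.diseases)
        for j, r in enumerate(net.ncrnas)
    ]


def _labels_vector(pairs) -> np.ndarray:
    if isinstance(pairs, np.ndarray):
        return pairs.astype(int)
    return np.array([p.label for p in pairs], dtype=int)


def partition_folds(
    pairs: Sequence[LabeledPair] | np.ndarray,
    k: int,
    seed: int | np.random.Generator,
    stratified: bool = True,
) -> list[np.ndarray]:
    """Split pair indices into k disjoint folds of near-equal size.

    Fold sizes differ by at most 1.  With ``stratified`` (default) the
    positives are dealt out first, cyclically, so per-fold positive
    counts also differ by at most 1.  ``pairs`` may be a LabeledPair
    sequence or a plain 0/1 label vector; returned folds are index
    arrays into it.
    """
    labels = _labels_vector(pairs)
    n = len(labels)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} pairs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if stratified:
        pos = rng.permutation(np.flatnonzero(labels == 1))
        neg = rng.permutation(np.flatnonzero(labels == 0))
        order = np.concatenate([pos, neg])
    else:
        order = rng.permutation(n)
    fold_cycle = rng.permutation(k)
    folds: list[list[int]] = [[] for _ in range(k)]
    for pos_in_order, idx in enumerate(order):
        folds[fold_cycle[pos_in_order % k]].append(int(idx))
    return [np.array(sorted(f), dtype=int) for f in folds]


def cut_links(
    net: TripartiteNetwork,
    test_pairs: Sequence[LabeledPair] | Sequence[tuple[int, int]],
    cut_mode: str = "tr_edge",
) -> TripartiteNetwork:
    """Disconnect every test pair that is connected through targets.

    For each test pair (d, r) and each target t adjacent to both, the
    target-ncRNA edge (t, r) is removed (and the disease-target edge
    (d, t) as well when ``cut_mode="both"``).  The input network is not
    mutated.  After cutting, no cut pair retains a disease-target-ncRNA
    path.
    """
    if cut_mode not in ("tr_edge", "both"):
        raise ValueError(f"unknown cut_mode {cut_mode!r}")
    out = net.copy()
    d_index = {d: i for i, d in enumerate(net.diseases)}
    r_index = {r: j for j, r in enumerate(net.ncrnas)}
    for pair in test_pairs:
        if isinstance(pair, LabeledPair):
            d, r = d_index[pair.disease_id], r_index[pair.ncrna_id]
        else:
            d, r = pair
        bridging = np.flatnonzero((net.A_DT[d] > 0) & (net.A_TR[:, r] > 0))
        out.A_TR[bridging, r] = 0.0
        if cut_mode == "both":
            out.A_DT[d, bridging] = 0.0
    return out


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC (Mann-Whitney with midrank ties) plus ROC curve points.

    Requires at least one positive and one negative label.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both a positive and a negative label")
    ranks = rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, s)
    return float(auc), fpr, tpr


def _interp_roc(fpr: np.ndarray, tpr: np.ndarray) -> np.ndarray:
    return np.interp(ROC_GRID, fpr, tpr)


def _fold_partitions(
    labels: np.ndarray, cfg: CVConfig
) -> list[list[np.ndarray]]:
    """One fold partition per repeat, derived deterministically from cfg.seed."""
    return [
        partition_folds(
            labels, cfg.k, np.random.default_rng([cfg.seed, rep]), cfg.stratified
        )
        for rep in range(cfg.repeats)
    ]


def cross_validate(
    net: TripartiteNetwork,
    target_seqs: Sequence[SequenceRecord],
    ncrna_seqs: Sequence[SequenceRecord],
    cfg: CVConfig,
    kernels: tuple[KernelMatrix, KernelMatrix] | None = None,
    folds_per_repeat: list[list[np.ndarray]] | None = None,
) -> EvaluationReport:
    """Repeated k-fold link-cut cross-validation of the scorer.

    Features and kernels depend only on the sequences (never held out)
    and are computed once; per fold, the connecting edges of positive
    test pairs are cut, the network is re-scored, and only the fold's
    pairs enter the ROC.  Folds whose pairs are single-class are skipped
    with a warning.  ``kernels``/``folds_per_repeat`` let grid search
    share work across calls.
    """
    labels_mat = association_labels(net)
    true_flat = labels_mat.ravel()
    d_idx, r_idx = np.divmod(np.arange(true_flat.size), net.p)
    eval_labels = true_flat
    if cfg.permute_labels:
        eval_labels = np.random.default_rng([cfg.seed, 999]).permutation(true_flat)
    if kernels is None:
        fm_t, fm_r = build_standardized_features(net, target_seqs, ncrna_seqs, cfg.l)
        kernels = kernel_pair(
            fm_t, fm_r, cfg.sigma1, cfg.sigma2, cfg.kernel, cfg.degree, cfg.sigma_assignment
        )
    k_t, k_r = kernels
    if folds_per_repeat is None:
        folds_per_repeat = _fold_partitions(eval_labels, cfg)

    aucs: list[float] = []
    tprs: list[np.ndarray] = []
    skipped = 0
    for folds in folds_per_repeat:
        for fold in folds:
            if cfg.cut_links:
                test_pairs = list(zip(d_idx[fold], r_idx[fold]))
                cut_net = cut_links(net, test_pairs, cfg.cut_mode)
                a_dt, a_tr = cut_net.A_DT, cut_net.A_TR
            else:
                a_dt, a_tr = net.A_DT, net.A_TR
            _, p = score_network(a_dt, a_tr, k_t, k_r, cfg.layer2_degree)
            fold_scores = p[d_idx[fold], r_idx[fold]]
            fold_labels = eval_labels[fold]
            if fold_labels.min() == fold_labels.max():
                logger.warning("skipping single-class fold (%d pairs)", len(fold))
                skipped += 1
                continue
            auc, fpr, tpr = roc_auc(fold_scores, fold_labels)
            aucs.append(auc)
            tprs.append(_interp_roc(fpr, tpr))
    if not aucs:
        raise ValueError("no fold produced both classes; cannot evaluate")
    mean_tpr = np.mean(tprs, axis=0)
    return EvaluationReport(
        fold_aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        fpr=ROC_GRID.copy(),
        tpr=mean_tpr,
        skipped_folds=skipped,
        sigma1=cfg.sigma1,
        sigma2=cfg.sigma2,
        config=asdict(cfg),
    )


def grid_search_sigmas(
    net: TripartiteNetwork,
    target_seqs: Sequence[SequenceRecord],
    ncrna_seqs: Sequence[SequenceRecord],
    cfg: CVConfig,
    grid_sigma1: Sequence[float] = SIGMA_GRID,
    grid_sigma2: Sequence[float] = SIGMA_GRID,
    point_evaluator: Callable[[float, float], float] | None = None,
) -> GridSearchResult:
    """Exhaustive (sigma1, sigma2) search maximizing mean CV AUC.

    Fold partitions are shared across all grid points, and each
    bandwidth's kernel is computed once per axis.  Ties are broken by
    the lexicographically smaller (sigma1, sigma2).  ``point_evaluator``
    replaces the CV evaluation of a single grid point (used in tests).
    """
    grid_sigma1 = tuple(grid_sigma1)
    grid_sigma2 = tuple(grid_sigma2)
    auc_grid = np.zeros((len(grid_sigma1), len(grid_sigma2)))

    if point_evaluator is None:
        labels = association_labels(net).ravel()
        eval_labels = labels
        if cfg.permute_labels:
            eval_labels = np.random.default_rng([cfg.seed, 999]).permutation(labels)
        folds = _fold_partitions(eval_labels, cfg)
        fm_t, fm_r = build_standardized_features(net, target_seqs, ncrna_seqs, cfg.l)
        if cfg.kernel == "rbf":
            # Squared distances are sigma-independent; compute them once and
            # rebuild each axis's kernel as exp(-gamma * d2).
            from scipy.spatial.distance import pdist, squareform

            d2_t = squareform(pdist(fm_t.values, metric="sqeuclidean"))
            d2_r = squareform(pdist(fm_r.values, metric="sqeuclidean"))

            def _rbf(d2: np.ndarray, ids: list[str], sigma: float) -> KernelMatrix:
                k = np.exp(-d2 / (2.0 * sigma**2))
                np.fill_diagonal(k, 1.0)
                return KernelMatrix(ids, k)

            axis_cache: dict[tuple[str, float], KernelMatrix] = {}

            def _kernels_for(s1: float, s2: float):
                s_t, s_r = (s1, s2) if cfg.sigma_assignment == "layer" else (s2, s1)
                if ("t", s_t) not in axis_cache:
                    axis_cache[("t", s_t)] = _rbf(d2_t, fm_t.entity_ids, s_t)
                if ("r", s_r) not in axis_cache:
                    axis_cache[("r", s_r)] = _rbf(d2_r, fm_r.entity_ids, s_r)
                return axis_cache[("t", s_t)], axis_cache[("r", s_r)]

        else:
            fixed = kernel_pair(
                fm_t, fm_r, 0.5, 0.5, cfg.kernel, cfg.degree, cfg.sigma_assignment
            )

            def _kernels_for(s1: float, s2: float):
                return fixed

        def point_evaluator(s1: float, s2: float) -> float:
            point_cfg = CVConfig(**{**asdict(cfg), "sigma1": s1, "sigma2": s2})
            report = cross_validate(
                net, target_seqs, ncrna_seqs, point_cfg,
                kernels=_kernels_for(s1, s2), folds_per_repeat=folds,
            )
            return report.mean_auc

    best: tuple[float, float, float] | None = None  # (-auc, s1, s2) minimized
    for i, s1 in enumerate(grid_sigma1):
        for j, s2 in enumerate(grid_sigma2):
            auc = point_evaluator(s1, s2)
            auc_grid[i, j] = auc
            cand = (-auc, s1, s2)
            if best is None or cand < best:
                best = cand
        logger.info("grid search: sigma1=%.1f done (best AUC so far %.4f)", s1, -best[0])
    assert best is not None
    return GridSearchResult(
        sigma1=best[1],
        sigma2=best[2],
        mean_auc=-best[0],
        grid_sigma1=grid_sigma1,
        grid_sigma2=grid_sigma2,
        auc_grid=auc_grid,
    )
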