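"""Conditional-MRF energy on the voxel lattice and alpha-expansion minimisation.

The energy over a labelling x is

    E(x) = sum_i u_{i;x_i}  +  sum_{(i,j)} w_{ij; x_i x_j}

with unary potentials u from the label densities and Potts-style pairwise
potentials that are zero for equal labels and, for differing labels,

    w_ij = (1 / dist(i, j)) * (lambda0 + lambda1 * exp(-||z_i - z_j||^2 / (2 beta)))

where z are the local-entropy observations.  dist is measured in units of
the in-plane pixel size: 1 within a slice, dz/dx between slices, so with
10 um slice spacing and 0.5 um pixels a between-slice edge carries 1/20 of
the in-plane weight.  Larger beta gives a smoother labelling, smaller beta a
rougher one.  lambda0/lambda1 are set from the unary range so unary and
pairwise terms share the same scale.

Minimisation is by alpha-expansion: each move fixes a label alpha and solves
a binary "keep current label vs switch to alpha" problem exactly as a
minimum s-t cut; Potts potentials make every move submodular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .density_model import UnaryField
from .entropy_filter import EntropyStack
from .io_stack import BACKGROUND, CAF, TUMOUR, LabelMap

#: capacities are scaled to integers by this factor for the max-flow solver;
#: the solver works in int32, so the scale shrinks if capacities would overflow
_CAPACITY_SCALE = 100_000_000

DEFAULT_BETA = 1.0 / 40.0  # the immunofluorescence preset; see cli presets

#: named beta presets corresponding to the three imaging protocols
BETA_PRESETS = {"if": 1.0 / 40.0, "live": 1.0 / 50.0, "fak": 1.0 / 60.0}


@dataclass(frozen=True)
class PairwiseParams:
    """Parameters of the pairwise potential.

    ``neighbour_offsets`` maps each lattice offset (dz, dy, dx) to its
    distance in units of the in-plane pixel size.
    """

    lambda0: float
    lambda1: float
    beta: float
    neighbour_offsets: tuple = ()

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be non-negative")
        for (_, _, _), dist in self.neighbour_offsets:
            if dist <= 0:
                raise ValueError("neighbour distances must be positive")


def neighbour_offsets_6(anisotropy: float) -> tuple:
    """Forward half of the 6-neighbourhood with distances: in-plane 1, z dz/dx."""
    return (((1, 0, 0), float(anisotropy)), ((0, 1, 0), 1.0), ((0, 0, 1), 1.0))


def neighbour_offsets_4() -> tuple:
    """Forward half of the in-plane 4-neighbourhood (2D / single-slice mode)."""
    return (((0, 1, 0), 1.0), ((0, 0, 1), 1.0))


def set_lambdas(unary: UnaryField) -> tuple[float, float]:
    """lambda0 = min unary, lambda1 = max - min, so both term families share a range."""
    if unary.u.size == 0:
        raise ValueError("empty unary field")
    lo = float(unary.u.min())
    hi = float(unary.u.max())
    return lo, hi - lo


def pairwise_weight(z_i: np.ndarray, z_j: np.ndarray, dist: float,
                    params: PairwiseParams) -> float:
    """Pairwise cost for *differing* labels at one edge (equal labels cost 0).

    The weight is floored at zero: lambda0 = min unary can be negative when
    a label density peaks above 1 (very concentrated background entropy),
    and a negative differing-label cost would leave the Potts family and
    break the submodularity the expansion moves rely on.  The floor is the
    minimal projection back onto valid Potts weights.
    """
    if dist <= 0:
        raise ValueError("dist must be positive")
    d2 = float(np.sum((np.asarray(z_i, dtype=float) - np.asarray(z_j, dtype=float)) ** 2))
    w = (params.lambda0 + params.lambda1 * np.exp(-d2 / (2.0 * params.beta))) / dist
    return max(w, 0.0)


@dataclass
class EnergyModel:
    """Unary field + pairwise rule + observations over one voxel lattice."""

    unary: UnaryField
    params: PairwiseParams
    observations: EntropyStack

    #: cached per-offset edge-weight grids, built lazily
    _edge_weights: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.unary.u.shape[:3] != self.observations.values.shape[:3]:
            raise ValueError("unary and observation shapes differ")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.unary.u.shape[:3]

    def edge_weights(self, offset: tuple, dist: float) -> np.ndarray:
        """Grid of w_ij for the forward offset; entry [i] pairs voxel i with i+offset."""
        key = offset
        if key not in self._edge_weights:
            z = self.observations.values
            a = _shift_pair(z, offset)
            d2 = ((a[0] - a[1]) ** 2).sum(axis=-1)
            w = (self.params.lambda0
                 + self.params.lambda1 * np.exp(-d2 / (2.0 * self.params.beta))) / dist
            # same zero floor as pairwise_weight: stay in the Potts family
            self._edge_weights[key] = np.maximum(w, 0.0)
        return self._edge_weights[key]


def _shift_pair(arr: np.ndarray, offset: tuple):
    """Views (arr_i, arr_j) of all voxel pairs (i, i+offset) inside the grid."""
    dz, dy, dx = offset
    sl_i = tuple(slice(0, arr.shape[k] - o) if o else slice(None)
                 for k, o in enumerate((dz, dy, dx)))
    sl_j = tuple(slice(o, None) if o else slice(None)
                 for k, o in enumerate((dz, dy, dx)))
    return arr[sl_i], arr[sl_j]


def total_energy(labelmap: LabelMap, model: EnergyModel) -> float:
    """E(x): unary sum plus pairwise sum over each neighbouring pair once."""
    labels = labelmap.labels
    if labels.shape != model.grid_shape:
        raise ValueError("label map shape does not match model")
    nz, ny, nx = labels.shape
    zz, yy, xx = np.indices(labels.shape, sparse=True)
    energy = float(model.unary.u[zz, yy, xx, labels].sum())
    for offset, dist in model.params.neighbour_offsets:
        li, lj = _shift_pair(labels, offset)
        w = model.edge_weights(offset, dist)
        energy += float(w[li != lj].sum())
    return energy


def min_st_cut(capacities: csr_matrix, source: int, sink: int):
    """Minimum s-t cut of a directed capacitated graph.

    Float capacities are scaled to int64 for the max-flow solver; the
    source-side set is recovered by BFS over positive residual capacities.
    Returns ``(cut_value, source_side_bool_array)``.
    """
    cap = csr_matrix(capacities, dtype=np.float64)
    if cap.data.size and cap.data.min() < 0:
        raise ValueError("negative capacity")
    scale = float(_CAPACITY_SCALE)
    max_cap = cap.data.max() if cap.data.size else 0.0
    if max_cap * scale >= 2**31 - 1:
        scale = (2**31 - 1) / (max_cap * 1.01)
    scaled = csr_matrix((np.round(cap.data * scale).astype(np.int64),
                         cap.indices, cap.indptr), shape=cap.shape)
    res = maximum_flow(scaled, source, sink)
    residual = scaled - res.flow
    residual.data = np.where(residual.data > 0, residual.data, 0)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, source, directed=True,
                                return_predecessors=False)
    source_side = np.zeros(cap.shape[0], dtype=bool)
    source_side[order] = True
    if source_side[sink]:
        raise RuntimeError("max-flow residual still connects source to sink")
    return res.flow_value / scale, source_side


def _expansion_move(labels: np.ndarray, alpha: int, model: EnergyModel) -> np.ndarray:
    """One alpha-expansion move; returns the proposed labelling.

    Binary problem per voxel: y=0 keep current label, y=1 switch to alpha.
    Voxels already labelled alpha are fixed (kept out of the graph; their
    pairwise influence folds into the neighbours' keep-cost).  The pairwise
    table (A, B, C, D) = (w*[x_i!=x_j], w*[x_i!=a], w*[a!=x_j], 0) is
    decomposed into t-links theta_i(1) += C-A, theta_j(1) += D-C and an edge
    i->j of capacity B+C-A-D (>= 0 for non-negative Potts weights).
    """
    grid_shape = labels.shape
    active = labels != alpha
    n_active = int(active.sum())
    if n_active == 0:
        return labels.copy()
    node_id = np.full(grid_shape, -1, dtype=np.int64)
    node_id[active] = np.arange(n_active)

    u = model.unary.u
    theta0 = u[active][np.arange(n_active), labels[active]].astype(np.float64)
    theta1 = u[active, alpha].astype(np.float64)

    edge_src, edge_dst, edge_cap = [], [], []
    for offset, dist in model.params.neighbour_offsets:
        w = model.edge_weights(offset, dist)
        ai, aj = _shift_pair(active, offset)
        li, lj = _shift_pair(labels, offset)
        ni, nj = _shift_pair(node_id, offset)

        both = ai & aj
        if both.any():
            wb = w[both]
            same = (li[both] == lj[both])
            # theta_i(1) += C - A = w * [x_i == x_j]; theta_j(1) += D - C = -w
            np.add.at(theta1, ni[both], np.where(same, wb, 0.0))
            np.add.at(theta1, nj[both], -wb)
            cap = wb * np.where(same, 2.0, 1.0)  # B + C - A - D
            if cap.size and cap.min() < -1e-12:
                raise AssertionError("non-submodular expansion move")
            edge_src.append(ni[both])
            edge_dst.append(nj[both])
            edge_cap.append(np.maximum(cap, 0.0))
        # active i, fixed j (x_j == alpha): keeping x_i costs w, switching 0
        only_i = ai & ~aj
        if only_i.any():
            np.add.at(theta0, ni[only_i], w[only_i])
        only_j = ~ai & aj
        if only_j.any():
            np.add.at(theta0, nj[only_j], w[only_j])

    # Cut convention: i on the source side <=> y_i = 0 (keep).  Then the cut
    # pays cap(i->t) for y_i=0, cap(s->i) for y_i=1, and the pairwise edge
    # i->j exactly on (y_i=0, y_j=1).  t-links are normalized by subtracting
    # min(theta0, theta1) per node so all capacities are non-negative.
    net = theta1 - theta0
    source, sink = n_active, n_active + 1
    s_cap = np.maximum(net, 0.0)
    t_cap = np.maximum(-net, 0.0)

    src = [np.full(n_active, source), np.arange(n_active)]
    dst = [np.arange(n_active), np.full(n_active, sink)]
    caps = [s_cap, t_cap]
    if edge_src:
        src.append(np.concatenate(edge_src))
        dst.append(np.concatenate(edge_dst))
        caps.append(np.concatenate(edge_cap))

    graph = csr_matrix((np.concatenate(caps),
                        (np.concatenate(src), np.concatenate(dst))),
                       shape=(n_active + 2, n_active + 2))
    _, source_side = min_st_cut(graph, source, sink)

    proposed = labels.copy()
    switch = np.zeros(n_active, dtype=bool)
    switch[:] = ~source_side[:n_active]
    proposed[active] = np.where(switch, alpha, labels[active])
    return proposed


def alpha_expansion(model: EnergyModel, init: LabelMap | None = None,
                    max_sweeps: int = 10, seed: int = 0,
                    log: list | None = None) -> LabelMap:
    """Minimise the MRF energy by repeated alpha-expansion sweeps.

    Sweeps cycle alpha over (background, tumour, CAF); each move is solved
    as a min s-t cut and accepted only if it strictly lowers the total
    energy (ties keep the current labelling).  Terminates when a full sweep
    accepts nothing or after ``max_sweeps``.  Default initialisation is the
    per-voxel argmin of the unaries (the 'mixtures' labelling), so the final
    energy never exceeds the mixtures energy.

    ``log``, if given, collects one ``(alpha, delta_energy)`` tuple per
    accepted move.
    """
    spacing = model.observations.spacing
    if init is None:
        init = LabelMap(np.argmin(model.unary.u, axis=-1).astype(np.uint8), spacing)
    labels = init.labels.copy()
    current = total_energy(LabelMap(labels, spacing), model)
    for _ in range(max_sweeps):
        accepted_any = False
        for alpha in (BACKGROUND, TUMOUR, CAF):
            proposed = _expansion_move(labels, alpha, model)
            if np.array_equal(proposed, labels):
                continue
            e = total_energy(LabelMap(proposed, spacing), model)
            if e < current:
                if log is not None:
                    log.append((alpha, e - current))
                labels, current = proposed, e
                accepted_any = True
        if not accepted_any:
            break
    return LabelMap(labels, spacing)
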