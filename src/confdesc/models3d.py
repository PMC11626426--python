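"""3D conformer-graph surrogate regressors (directional message passing).

Conformers become radial graphs: every atom pair closer than a distance
cutoff is an edge, covalent or not, and hydrogens are explicit.  Atom nodes
reuse the 2D one-hot featurizer; bonds carry no features.  Following the
DimeNet++ design, messages live on directed edges and interaction blocks mix
each incoming message m_kj into m_ji through a radial basis of the distance
d_kj and an angular (cosine) basis of the angle k-j-i, which makes
predictions exactly invariant to rigid rotation and translation of the input
geometry.

Training uses conformer augmentation: each of the (up to 20) ensemble
conformers is an independent sample carrying the same ensemble-level label.
At prediction time the per-conformer outputs are averaged (unweighted by
default) to suppress input-conformer noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import mean_absolute_error, r2_score

from . import nn
from .ensembles import ConformerEnsemble
from .features import ATOM_FEATURE_DIM, atom_features_with_h

log = logging.getLogger(__name__)

N_RBF = 16   # Gaussian radial basis functions on [0, cutoff]
N_ANG = 7    # cosine angular basis cos(n*theta), n = 0..6


@dataclass
class Radial3DGraph:
    """Distance-cutoff graph over one conformer geometry."""

    x: np.ndarray            # (n_atoms, ATOM_FEATURE_DIM)
    positions: np.ndarray    # (n_atoms, 3) angstrom
    edge_src: np.ndarray     # directed edges j -> i: source j
    edge_dst: np.ndarray     # destination i
    rbf: np.ndarray          # (n_edges, N_RBF) radial basis of d_ji
    trip_src: np.ndarray     # triplet (k->j, j->i): index of edge k->j
    trip_dst: np.ndarray     # index of edge j->i
    ang: np.ndarray          # (n_triplets, N_ANG) cosine basis of angle kji

    @property
    def n_atoms(self) -> int:
        return self.x.shape[0]


def _rbf_expand(d: np.ndarray, cutoff: float) -> np.ndarray:
    centers = np.linspace(0.0, cutoff, N_RBF)
    gamma = (N_RBF / cutoff) ** 2
    return np.exp(-gamma * (d[:, None] - centers[None, :]) ** 2)


def build_radial_graph(
    positions: np.ndarray,
    atom_x: np.ndarray,
    cutoff: float = 5.0,
) -> Radial3DGraph:
    """Exact pairwise-distance thresholding; symmetric directed edge set.

    Every pair (covalently bonded or not) with distance < cutoff becomes a
    directed edge in both orientations; self-edges are absent.
    """
    pos = np.asarray(positions, float)
    n = len(pos)
    if n < 2:
        raise ValueError("radial graph needs at least 2 atoms")
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    mask = (dist < cutoff) & ~np.eye(n, dtype=bool)
    src, dst = np.nonzero(mask)  # edge j -> i with j=src, i=dst
    d = dist[src, dst]
    rbf = _rbf_expand(d, cutoff)

    # triplets: for edge e1 = (k->j) and edge e2 = (j->i) with k != i
    by_dst: dict[int, list[int]] = {}
    for e, j in enumerate(dst):
        by_dst.setdefault(int(j), []).append(e)
    t_src, t_dst, cos_ang = [], [], []
    for e2, (j, i) in enumerate(zip(src, dst)):
        for e1 in by_dst.get(int(j), ()):
            k = int(src[e1])
            if k == int(i):
                continue
            v1 = pos[k] - pos[j]
            v2 = pos[i] - pos[j]
            c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            t_src.append(e1)
            t_dst.append(e2)
            cos_ang.append(np.clip(c, -1.0, 1.0))
    theta = np.arccos(np.array(cos_ang)) if cos_ang else np.zeros(0)
    ang = np.cos(np.outer(theta, np.arange(N_ANG)))
    return Radial3DGraph(
        x=np.asarray(atom_x, float), positions=pos,
        edge_src=src.astype(np.intp), edge_dst=dst.astype(np.intp),
        rbf=rbf,
        trip_src=np.array(t_src, dtype=np.intp),
        trip_dst=np.array(t_dst, dtype=np.intp),
        ang=ang.reshape(len(t_src), N_ANG) if len(t_src) else np.zeros((0, N_ANG)),
    )


def graphs_from_ensemble(
    ensemble: ConformerEnsemble, cutoff: float = 5.0
) -> list[Radial3DGraph]:
    """One radial graph per conformer, sharing the ensemble's atom features."""
    if ensemble.mol is None:
        raise ValueError(
            f"ensemble {ensemble.molecule_id!r} carries no molecular graph; "
            "atom features need connectivity"
        )
    atom_x = atom_features_with_h(ensemble.mol)
    return [build_radial_graph(c.coords, atom_x, cutoff) for c in ensemble.conformers]


class _Batch3D:
    def __init__(self, graphs: list[Radial3DGraph], sample_idx: list[int],
                 readout_atoms: list[int] | None = None):
        xs, srcs, dsts, rbfs, tsrcs, tdsts, angs, batch_idx = [], [], [], [], [], [], [], []
        rows = []
        n_off = e_off = 0
        for g_i, g in enumerate(graphs):
            xs.append(g.x)
            srcs.append(g.edge_src + n_off)
            dsts.append(g.edge_dst + n_off)
            rbfs.append(g.rbf)
            tsrcs.append(g.trip_src + e_off)
            tdsts.append(g.trip_dst + e_off)
            angs.append(g.ang)
            batch_idx.append(np.full(g.n_atoms, g_i, dtype=np.intp))
            if readout_atoms is not None:
                rows.append(readout_atoms[g_i] + n_off)
            n_off += g.n_atoms
            e_off += len(g.edge_src)
        self.x = np.concatenate(xs, 0)
        self.src = np.concatenate(srcs)
        self.dst = np.concatenate(dsts)
        self.rbf = np.concatenate(rbfs, 0)
        self.trip_src = np.concatenate(tsrcs)
        self.trip_dst = np.concatenate(tdsts)
        self.ang = np.concatenate(angs, 0)
        self.batch = np.concatenate(batch_idx)
        self.n_nodes = n_off
        self.n_edges = e_off
        self.n_graphs = len(graphs)
        self.sample_idx = np.asarray(sample_idx, dtype=np.intp)
        self.readout_rows = np.asarray(rows, dtype=np.intp) if readout_atoms else None


class DimeNetLiteRegressor(BaseEstimator, RegressorMixin):
    """Conformer-ensemble property regressor on radial 3D graphs.

    ``X`` is a sequence of :class:`ConformerEnsemble` (cap them to the
    augmentation limit with :func:`confdesc.ensembles.cap_for_model` first);
    ``y`` one ensemble-level target per molecule.  Train/validation splits are
    made by molecule, never by conformer, and validation/test predictions
    average over each ensemble's conformers.

    Parameters mirror :class:`confdesc.models2d.GINERegressor`; ``cutoff`` is
    the radial edge threshold in angstrom and ``n_blocks`` the number of
    directional interaction blocks.  ``aggregation`` pools edge states into
    nodes and nodes into the molecule: 'mean' (default; suits intensive,
    size-independent descriptors) or 'sum' (suits extensive, counting-type
    targets).  ``boltzmann_average=True`` switches the test-time conformer
    average from unweighted to Boltzmann-weighted.
    """

    def __init__(
        self,
        hidden: int = 64,
        n_blocks: int = 2,
        cutoff: float = 5.0,
        readout: str = "molecule",
        aggregation: str = "mean",
        epochs: int = 200,
        lr: float = 3e-3,
        batch_size: int = 16,
        patience: int = 25,
        val_fraction: float = 0.1,
        standardize: bool = True,
        boltzmann_average: bool = False,
        seed: int = 0,
        verbose: int = 0,
    ):
        self.hidden = hidden
        self.n_blocks = n_blocks
        self.cutoff = cutoff
        self.readout = readout
        self.aggregation = aggregation
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.standardize = standardize
        self.boltzmann_average = boltzmann_average
        self.seed = seed
        self.verbose = verbose

    def _init_params(self, rng: np.random.Generator) -> dict:
        d = self.hidden
        p = {
            "embed": nn.Linear(ATOM_FEATURE_DIM, d, rng),
            "m_src": nn.Linear(d, d, rng),
            "m_dst": nn.Linear(d, d, rng),
            "m_rbf": nn.Linear(N_RBF, d, rng),
            "blocks": [
                {
                    "t": nn.Linear(d, d, rng),
                    "ang": nn.Linear(N_ANG, d, rng),
                    "upd_m": nn.Linear(d, d, rng),
                    "upd_a": nn.Linear(d, d, rng),
                }
                for _ in range(self.n_blocks)
            ],
            "out_edge": nn.Linear(d, d, rng),
            "head": nn.MLP([d, d, 1], rng, activation=nn.silu),
        }
        return p

    def _parameters(self) -> list:
        p = self._params
        out = []
        for key in ("embed", "m_src", "m_dst", "m_rbf", "out_edge"):
            out += p[key].parameters
        for blk in p["blocks"]:
            for lay in blk.values():
                out += lay.parameters
        out += p["head"].parameters
        return out

    def _forward(self, b: _Batch3D) -> nn.Tensor:
        p = self._params
        h = nn.silu(p["embed"](nn.Tensor(b.x)))
        rbf = nn.Tensor(b.rbf)
        m = nn.silu(
            p["m_src"](nn.take(h, b.src)) + p["m_dst"](nn.take(h, b.dst))
            + p["m_rbf"](rbf)
        )
        for blk in p["blocks"]:
            if len(b.trip_src):
                t = nn.silu(blk["t"](nn.take(m, b.trip_src))) * blk["ang"](nn.Tensor(b.ang))
                agg = nn.segment_sum(t, b.trip_dst, b.n_edges)
                m = m + nn.silu(blk["upd_m"](m) + blk["upd_a"](agg))
            else:
                m = m + nn.silu(blk["upd_m"](m))
        agg_fn = nn.segment_mean if self.aggregation == "mean" else nn.segment_sum
        node = agg_fn(nn.silu(p["out_edge"](m)), b.dst, b.n_nodes)
        if self.readout == "molecule":
            pooled = agg_fn(node, b.batch, b.n_graphs)
        elif self.readout == "atom":
            if b.readout_rows is None:
                raise ValueError("atom readout requires readout atom indices")
            pooled = nn.take(node, b.readout_rows)
        else:
            raise ValueError(f"unknown readout {self.readout!r}")
        return p["head"](pooled)

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y, dtype=float).ravel()
        ensembles: list[ConformerEnsemble] = list(X)
        if len(ensembles) != len(y):
            raise ValueError("X and y length mismatch")
        graphs_per_mol: list[list[Radial3DGraph]] = []
        kept = []
        for i, ens in enumerate(ensembles):
            if len(ens) == 0:
                log.warning("molecule %s has no conformers; excluded", ens.molecule_id)
                continue
            graphs_per_mol.append(graphs_from_ensemble(ens, self.cutoff))
            kept.append(i)
        y = y[np.array(kept)]
        n = len(graphs_per_mol)
        if n < 2:
            raise ValueError("need at least 2 molecules with conformers")

        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n)  # split by molecule, never by conformer
        n_val = max(1, int(round(self.val_fraction * n))) if self.val_fraction > 0 else 0
        val_idx, train_idx = perm[:n_val], perm[n_val:]

        if self.standardize:
            self.y_mean_ = float(y[train_idx].mean())
            self.y_std_ = float(y[train_idx].std()) or 1.0
        else:
            self.y_mean_, self.y_std_ = 0.0, 1.0
        yz = (y - self.y_mean_) / self.y_std_

        def flat_batch(mol_idx):
            graphs, sample = [], []
            for mi in mol_idx:
                for g in graphs_per_mol[mi]:
                    graphs.append(g)
                    sample.append(mi)
            return _Batch3D(graphs, sample)

        # molecule-level minibatches, prebuilt once (bounded autodiff memory)
        chunks = [
            train_idx[i : i + self.batch_size]
            for i in range(0, len(train_idx), self.batch_size)
        ]
        train_batches = [flat_batch(c) for c in chunks]
        train_targets = [yz[b.sample_idx] for b in train_batches]
        val_batch = flat_batch(val_idx) if n_val else None

        self._params = self._init_params(rng)
        opt = nn.Adam(self._parameters(), lr=self.lr)
        best_val, best_snap, stale = np.inf, None, 0
        self.history_ = []
        for epoch in range(self.epochs):
            epoch_loss = 0.0
            for b, t in zip(train_batches, train_targets):
                opt.zero_grad()
                pred = self._forward(b)
                loss = nn.mse(pred, t[:, None])
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(t)
            loss_val = epoch_loss / sum(len(t) for t in train_targets)

            if val_batch is not None:
                # conformer-averaged validation predictions per molecule
                raw = self._forward(val_batch).data.ravel()
                val_mae = 0.0
                for mi in val_idx:
                    sel = val_batch.sample_idx == mi
                    val_mae += abs(raw[sel].mean() - yz[mi])
                val_mae /= len(val_idx)
            else:
                val_mae = loss_val
            self.history_.append({"epoch": epoch, "train_mse": loss_val,
                                  "val_mae": float(val_mae)})
            if val_mae < best_val - 1e-9:
                best_val, best_snap, stale = val_mae, opt.state_snapshot(), 0
            else:
                stale += 1
                if stale > self.patience:
                    break
            if self.verbose and epoch % 10 == 0:
                log.info("epoch %d loss %.5f val_mae %.5f", epoch, loss_val, val_mae)
        if best_snap is not None:
            opt.load_snapshot(best_snap)
        self.n_molecules_ = n
        return self

    def predict_conformers(self, ensemble: ConformerEnsemble) -> np.ndarray:
        """Raw per-conformer predictions for one ensemble."""
        if not hasattr(self, "_params"):
            raise RuntimeError("model is not fitted")
        graphs = graphs_from_ensemble(ensemble, self.cutoff)
        batch = _Batch3D(graphs, list(range(len(graphs))))
        return self._forward(batch).data.ravel() * self.y_std_ + self.y_mean_

    def predict_averaged(self, ensemble: ConformerEnsemble) -> float:
        """Test-time conformer averaging (unweighted by default)."""
        if len(ensemble) == 0:
            raise ValueError(f"ensemble {ensemble.molecule_id!r} is empty")
        preds = self.predict_conformers(ensemble)
        if self.boltzmann_average:
            from .condense import boltzmann_weights

            w = boltzmann_weights(ensemble.rel_energies)
            return float(w @ preds)
        return float(preds.mean())

    def predict(self, X) -> np.ndarray:
        return np.array([self.predict_averaged(ens) for ens in X])

    def evaluate(self, X, y) -> dict[str, float]:
        y = np.asarray(y, dtype=float).ravel()
        pred = self.predict(X)
        return {
            "r2": float(r2_score(y, pred)),
            "mae": float(mean_absolute_error(y, pred)),
        }


def predict_3d_averaged(model: DimeNetLiteRegressor, ensemble: ConformerEnsemble,
                        cutoff: float | None = None) -> float:
    """Functional wrapper over :meth:`DimeNetLiteRegressor.predict_averaged`."""
    if cutoff is not None and cutoff != model.cutoff:
        raise ValueError("cutoff must match the fitted model's cutoff")
    return model.predict_averaged(ensemble)
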