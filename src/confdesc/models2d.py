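"""2D graph-network surrogate regressors (GINE-style message passing).

One regressor is trained per condensed descriptor.  Molecules are heavy-atom
graphs with one-hot atom/bond features; message passing follows the graph
isomorphism network with edge features (GINE): each round aggregates
ReLU(h_j + W_e e_ij) over neighbors j, combines with (1 + eps) h_i and applies
a two-layer MLP.  Readout is sum pooling for molecule-level targets, the
mapped role atom's state for atom-level targets, or the summed states of a
role pair for bond-level targets.

The estimator follows the scikit-learn protocol (``fit``/``predict``/
``get_params``); ``X`` is a sequence of SMILES strings or RDKit molecules.
"""

from __future__ import annotations

import logging

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import mean_absolute_error, r2_score

from . import nn
from .features import (
    ATOM_FEATURE_DIM,
    BOND_FEATURE_DIM,
    FeaturizationError,
    Graph2D,
    featurize_2d,
)
from .moiety import MoietyError, builtin_moiety, map_moiety, mol_with_hs

log = logging.getLogger(__name__)


class _Batch:
    """Disjoint union of graphs with per-graph readout bookkeeping."""

    def __init__(self, graphs: list[Graph2D], readout_atoms: list[list[int]] | None):
        xs, srcs, dsts, eattrs, batch_idx = [], [], [], [], []
        readout_rows: list[list[int]] = []
        offset = 0
        for g_i, g in enumerate(graphs):
            xs.append(g.x)
            srcs.append(g.edge_index[0] + offset)
            dsts.append(g.edge_index[1] + offset)
            eattrs.append(g.edge_attr)
            batch_idx.append(np.full(g.n_atoms, g_i, dtype=np.intp))
            if readout_atoms is not None:
                readout_rows.append([a + offset for a in readout_atoms[g_i]])
            offset += g.n_atoms
        self.x = np.concatenate(xs, axis=0)
        self.src = np.concatenate(srcs)
        self.dst = np.concatenate(dsts)
        self.edge_attr = np.concatenate(eattrs, axis=0)
        self.batch = np.concatenate(batch_idx)
        self.n_graphs = len(graphs)
        self.n_nodes = offset
        self.readout_rows = readout_rows if readout_atoms is not None else None


class GINERegressor(BaseEstimator, RegressorMixin):
    """Single-target molecular property regressor with GINE convolutions.

    Parameters
    ----------
    hidden : width of the node embeddings.
    n_layers : number of message-passing rounds.
    readout : 'molecule' (sum pooling), 'atom' (state of one mapped role
        atom) or 'bond' (summed projections of a role pair).
    moiety, roles : for atom/bond readouts, the built-in moiety name and the
        role (or role pair) whose atom state is read out, e.g.
        ``moiety='primary_amine', roles=('N1',)``.  Hydrogen roles are not
        addressable on the heavy-atom graph.
    epochs, lr, patience : full-batch Adam budget, learning rate and early
        stopping patience on validation MAE.
    val_fraction : fraction of molecules held out (by seeded shuffle) for
        early stopping.
    seed : reproducibility; identical seeds give identical fits.
    """

    def __init__(
        self,
        hidden: int = 64,
        n_layers: int = 3,
        readout: str = "molecule",
        moiety: str | None = None,
        roles: tuple = (),
        epochs: int = 400,
        lr: float = 3e-3,
        patience: int = 30,
        val_fraction: float = 0.1,
        standardize: bool = True,
        seed: int = 0,
        verbose: int = 0,
    ):
        self.hidden = hidden
        self.n_layers = n_layers
        self.readout = readout
        self.moiety = moiety
        self.roles = roles
        self.epochs = epochs
        self.lr = lr
        self.patience = patience
        self.val_fraction = val_fraction
        self.standardize = standardize
        self.seed = seed
        self.verbose = verbose

    # -- featurization -------------------------------------------------------
    def _prepare(self, X) -> tuple[list[Graph2D], list[list[int]] | None, np.ndarray]:
        """Featurize; returns graphs, readout atoms and indices of kept rows."""
        graphs, readout_atoms, kept = [], [], []
        want_atoms = self.readout in ("atom", "bond")
        if want_atoms and (self.moiety is None or not self.roles):
            raise ValueError("atom/bond readout requires moiety= and roles=")
        for i, item in enumerate(X):
            try:
                g = featurize_2d(item)
                rows: list[int] = []
                if want_atoms:
                    smiles = item if isinstance(item, str) else Chem.MolToSmiles(item)
                    mm = map_moiety(mol_with_hs(smiles), builtin_moiety(self.moiety))
                    n_heavy = g.n_atoms
                    for role in self.roles:
                        idx = mm.role_to_atom.get(role)
                        if idx is None or idx >= n_heavy:
                            raise MoietyError(
                                f"role {role} unmapped or not a heavy atom"
                            )
                        rows.append(idx)
                graphs.append(g)
                readout_atoms.append(rows)
                kept.append(i)
            except (FeaturizationError, MoietyError) as exc:
                log.warning("molecule %d excluded: %s", i, exc)
        return graphs, (readout_atoms if want_atoms else None), np.array(kept)

    # -- model ---------------------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict:
        d = self.hidden
        p = {
            "embed": nn.Linear(ATOM_FEATURE_DIM, d, rng),
            "edge": [nn.Linear(BOND_FEATURE_DIM, d, rng) for _ in range(self.n_layers)],
            "upd": [nn.MLP([d, d, d], rng) for _ in range(self.n_layers)],
            "eps": [nn.Parameter(np.zeros(1)) for _ in range(self.n_layers)],
            "head": nn.MLP([d, d, 1], rng),
        }
        if self.readout == "bond":
            p["bond_proj"] = [nn.Linear(d, d, rng), nn.Linear(d, d, rng)]
        return p

    def _parameters(self) -> list:
        p = self._params
        out = list(p["embed"].parameters) + list(p["head"].parameters) + p["eps"]
        for lay in p["edge"]:
            out += lay.parameters
        for lay in p["upd"]:
            out += lay.parameters
        if "bond_proj" in p:
            for lay in p["bond_proj"]:
                out += lay.parameters
        return out

    def _forward(self, batch: _Batch) -> nn.Tensor:
        p = self._params
        h = p["embed"](nn.Tensor(batch.x))
        for edge_lin, upd, eps in zip(p["edge"], p["upd"], p["eps"]):
            if len(batch.src):
                msg = nn.relu(nn.take(h, batch.src) + edge_lin(nn.Tensor(batch.edge_attr)))
                agg = nn.segment_sum(msg, batch.dst, batch.n_nodes)
                h = upd(h + eps * h + agg)
            else:
                h = upd(h + eps * h)
        if self.readout == "molecule":
            pooled = nn.segment_sum(h, batch.batch, batch.n_graphs)
        elif self.readout == "atom":
            rows = np.array([r[0] for r in batch.readout_rows], dtype=np.intp)
            pooled = nn.take(h, rows)
        elif self.readout == "bond":
            rows_a = np.array([r[0] for r in batch.readout_rows], dtype=np.intp)
            rows_b = np.array([r[1] for r in batch.readout_rows], dtype=np.intp)
            pa, pb = p["bond_proj"]
            pooled = pa(nn.take(h, rows_a)) + pb(nn.take(h, rows_b))
        else:
            raise ValueError(f"unknown readout {self.readout!r}")
        return p["head"](pooled)

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        graphs, readout_atoms, kept = self._prepare(X)
        if len(graphs) < 2:
            raise ValueError("need at least 2 featurizable molecules")
        y = y[kept]

        rng = np.random.default_rng(self.seed)
        n = len(graphs)
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n))) if self.val_fraction > 0 else 0
        val_idx, train_idx = perm[:n_val], perm[n_val:]

        if self.standardize:
            self.y_mean_ = float(y[train_idx].mean())
            self.y_std_ = float(y[train_idx].std()) or 1.0
        else:
            self.y_mean_, self.y_std_ = 0.0, 1.0
        yz = (y - self.y_mean_) / self.y_std_

        def subset(idx):
            return _Batch(
                [graphs[i] for i in idx],
                [readout_atoms[i] for i in idx] if readout_atoms is not None else None,
            )

        train_batch, val_batch = subset(train_idx), (subset(val_idx) if n_val else None)

        self._params = self._init_params(rng)
        params = self._parameters()
        opt = nn.Adam(params, lr=self.lr)
        best_val, best_snap, stale = np.inf, None, 0
        self.history_ = []
        for epoch in range(self.epochs):
            opt.zero_grad()
            pred = self._forward(train_batch)
            loss = nn.mse(pred, yz[train_idx][:, None])
            loss.backward()
            opt.step()

            if val_batch is not None:
                val_pred = self._forward(val_batch).data.ravel()
                val_mae = float(np.abs(val_pred - yz[val_idx]).mean())
            else:
                val_mae = float(loss.data)
            self.history_.append({"epoch": epoch, "train_mse": float(loss.data),
                                  "val_mae": val_mae})
            if val_mae < best_val - 1e-9:
                best_val, best_snap, stale = val_mae, opt.state_snapshot(), 0
            else:
                stale += 1
                if stale > self.patience:
                    break
            if self.verbose and epoch % 25 == 0:
                log.info("epoch %d loss %.5f val_mae %.5f", epoch, loss.data, val_mae)
        if best_snap is not None:
            opt.load_snapshot(best_snap)

        self.n_molecules_ = n
        train_pred = self._forward(train_batch).data.ravel() * self.y_std_ + self.y_mean_
        self.train_r2_ = float(r2_score(y[train_idx], train_pred))
        self.train_mae_ = float(mean_absolute_error(y[train_idx], train_pred))
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "_params"):
            raise RuntimeError("model is not fitted")
        out = np.full(len(X), np.nan)
        self.prediction_errors_: list[tuple[int, str]] = []
        graphs, readout_atoms, kept = self._prepare(X)
        for i in range(len(X)):
            if i not in set(kept.tolist()):
                self.prediction_errors_.append((i, "featurization or mapping failed"))
        if len(graphs):
            batch = _Batch(graphs, readout_atoms)
            pred = self._forward(batch).data.ravel() * self.y_std_ + self.y_mean_
            out[kept] = pred
        return out

    def evaluate(self, X, y) -> dict[str, float]:
        """R^2 and MAE on a labelled set (NaN-predicted molecules dropped)."""
        y = np.asarray(y, dtype=float).ravel()
        pred = self.predict(X)
        ok = ~np.isnan(pred)
        if ok.sum() < 2:
            raise ValueError("fewer than 2 valid predictions")
        return {
            "r2": float(r2_score(y[ok], pred[ok])),
            "mae": float(mean_absolute_error(y[ok], pred[ok])),
        }
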