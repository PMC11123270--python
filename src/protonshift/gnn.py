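"""Distance-edge graph featurization and the message-passing shift model.

The molecule becomes a graph whose nodes carry an element-type embedding and
whose edges carry a Gaussian radial expansion of the interatomic distance.
Edges connect every atom pair within a distance cutoff, plus every bonded
pair regardless of distance.  An edge network mixes endpoint node embeddings
with the distance embedding into per-edge gating features; T shared
message-passing steps let atoms exchange information (messages to the same
node are summed before a gated-recurrent node update); three dense readout
layers and a linear head map each node state to one chemical shift in ppm.

Layer inventory and trainable-flag semantics:

=================  =========================================  ==============
layer name         contents                                   fine-tune
=================  =========================================  ==============
node_embedding     element -> R^D table                       frozen
edge_embedding     RBF -> R^D dense map                       frozen
edge_net.0/.1      the two edge-network dense layers          trainable
mp                 message weights + GRU node-update weights  frozen
readout.0/.1/.2    dense layers (widths 256/256/128 default)  trainable
head               final scalar layer                         trainable
=================  =========================================  ==============

Exactly six layers are trainable in fine-tune mode; in scratch mode all are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .chem_io import MoleculeRecord, find_equivalent_hydrogens, PredictionResult

ELEMENT_VOCAB = ("H", "C", "N", "O", "S")
FINETUNE_TRAINABLE_LAYERS = ("edge_net.0", "edge_net.1",
                             "readout.0", "readout.1", "readout.2", "head")

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class GraphConfig:
    """Featurization and architecture hyperparameters.

    Defaults are the full-scale profile (256-wide node/edge features); the
    ``reduced()`` profile shrinks every width for CPU-scale runs.
    """

    cutoff: float = 4.0            # Angstrom; bonded pairs kept regardless
    n_rbf: int = 64                # Gaussian centers, evenly spaced on [0, cutoff]
    dim: int = 256                 # node/edge feature width D
    n_passes: int = 3              # message-passing iterations T (shared weights)
    readout_widths: tuple[int, int, int] = (256, 256, 128)

    @staticmethod
    def reduced() -> "GraphConfig":
        return GraphConfig(n_rbf=16, dim=64, readout_widths=(64, 64, 32))

    @property
    def rbf_centers(self) -> np.ndarray:
        return np.linspace(0.0, self.cutoff, self.n_rbf)

    @property
    def rbf_width(self) -> float:
        return self.cutoff / (self.n_rbf - 1)

    def to_dict(self) -> dict:
        return {"cutoff": self.cutoff, "n_rbf": self.n_rbf, "dim": self.dim,
                "n_passes": self.n_passes, "readout_widths": list(self.readout_widths)}

    @staticmethod
    def from_dict(d: dict) -> "GraphConfig":
        return GraphConfig(cutoff=d["cutoff"], n_rbf=d["n_rbf"], dim=d["dim"],
                           n_passes=d["n_passes"],
                           readout_widths=tuple(d["readout_widths"]))


@dataclass
class FeaturizedGraph:
    node_type: np.ndarray      # (N,) int index into ELEMENT_VOCAB
    edge_index: np.ndarray     # (E, 2) ordered (src, dst), 0-based
    edge_distance: np.ndarray  # (E,) Angstrom
    edge_rbf: np.ndarray       # (E, n_rbf) in [0, 1]
    edge_bonded: np.ndarray    # (E,) bool, True where the pair shares a bond
    h_mask: np.ndarray         # (N,) bool, True for hydrogens

    @property
    def n_nodes(self) -> int:
        return self.node_type.shape[0]


def rbf_expand(d, centers: np.ndarray, width: float) -> np.ndarray:
    """Gaussian expansion exp(-(d - mu_k)^2 / (2 width^2)); values in (0, 1]."""
    d = np.atleast_1d(np.asarray(d, dtype=np.float64))
    return np.exp(-((d[:, None] - centers[None, :]) ** 2) / (2.0 * width * width))


def build_graph(mol: MoleculeRecord, config: GraphConfig | None = None) -> FeaturizedGraph:
    """Featurize a 3D molecule into a symmetric distance-edge graph.

    Edges are all ordered pairs with distance <= cutoff, plus bonded pairs
    beyond the cutoff.  Raises for molecules with fewer than two atoms or
    elements outside the vocabulary.
    """
    config = config or GraphConfig()
    n = mol.n_atoms
    if n < 2:
        raise ValueError(f"{mol.id}: need at least 2 atoms to build a graph")
    try:
        node_type = np.array([ELEMENT_VOCAB.index(el) for _, el, _ in mol.atoms])
    except ValueError:
        bad = sorted({el for _, el, _ in mol.atoms} - set(ELEMENT_VOCAB))
        raise ValueError(f"{mol.id}: unsupported elements {bad}") from None
    dmat = np.linalg.norm(mol.coords[:, None, :] - mol.coords[None, :, :], axis=-1)
    within = dmat <= config.cutoff
    np.fill_diagonal(within, False)
    bonded = np.zeros((n, n), dtype=bool)
    for i, j, _ in mol.bonds:
        bonded[i - 1, j - 1] = bonded[j - 1, i - 1] = True
    src, dst = np.nonzero(within | bonded)
    edge_index = np.stack([src, dst], axis=1)
    edge_distance = dmat[src, dst]
    edge_rbf = rbf_expand(edge_distance, config.rbf_centers, config.rbf_width)
    h_mask = np.array([el == "H" for _, el, _ in mol.atoms])
    return FeaturizedGraph(node_type=node_type, edge_index=edge_index,
                           edge_distance=edge_distance, edge_rbf=edge_rbf,
                           edge_bonded=bonded[src, dst], h_mask=h_mask)


def batch_graphs(graphs: list[FeaturizedGraph]) -> FeaturizedGraph:
    """Concatenate graphs into one disjoint-union graph (node indices offset)."""
    offset = 0
    types, edges, dists, rbfs, bond, masks = [], [], [], [], [], []
    for g in graphs:
        types.append(g.node_type)
        edges.append(g.edge_index + offset)
        dists.append(g.edge_distance)
        rbfs.append(g.edge_rbf)
        bond.append(g.edge_bonded)
        masks.append(g.h_mask)
        offset += g.n_nodes
    return FeaturizedGraph(node_type=np.concatenate(types),
                           edge_index=np.concatenate(edges, axis=0),
                           edge_distance=np.concatenate(dists),
                           edge_rbf=np.concatenate(rbfs, axis=0),
                           edge_bonded=np.concatenate(bond),
                           h_mask=np.concatenate(masks))


# ---------------------------------------------------------------------------
# parameters

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def _he(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    # He init for ReLU layers; keeps activations alive in deep stacks
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


class ModelParams:
    """All weight arrays, per-layer trainable flags, and the output scaling.

    ``weights`` maps ``"<layer>.<array>"`` to ndarrays; ``trainable_flags``
    maps layer names to bools.  ``target_mean``/``target_std`` standardize the
    regression targets and are fixed at training time (never fine-tuned).
    """

    def __init__(self, config: GraphConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        D = config.dim
        w: dict[str, np.ndarray] = {}
        w["node_embedding.table"] = rng.normal(0.0, 0.3, size=(len(ELEMENT_VOCAB), D))
        # +1 input: the bonded-pair indicator channel alongside the RBF vector
        w["edge_embedding.W"] = _glorot(rng, config.n_rbf + 1, D)
        w["edge_embedding.b"] = np.zeros(D)
        w["edge_net.0.W"] = _he(rng, 3 * D, D)
        w["edge_net.0.b"] = np.zeros(D)
        w["edge_net.1.W"] = _he(rng, D, D)
        w["edge_net.1.b"] = np.zeros(D)
        w["mp.msg.W"] = _glorot(rng, D, D)
        for gate in ("z", "r", "h"):
            w[f"mp.gru.W{gate}"] = _glorot(rng, D, D)
            w[f"mp.gru.U{gate}"] = _glorot(rng, D, D)
            w[f"mp.gru.b{gate}"] = np.zeros(D)
        widths = (D,) + config.readout_widths
        for k in range(3):
            w[f"readout.{k}.W"] = _he(rng, widths[k], widths[k + 1])
            w[f"readout.{k}.b"] = np.zeros(widths[k + 1])
        w["head.W"] = _glorot(rng, widths[3], 1)
        w["head.b"] = np.zeros(1)
        self.weights = w
        self.trainable_flags: dict[str, bool] = {name: True for name in self.layer_names()}
        self.target_mean: float = 0.0
        self.target_std: float = 1.0

    @staticmethod
    def layer_names() -> tuple[str, ...]:
        return ("node_embedding", "edge_embedding", "edge_net.0", "edge_net.1",
                "mp", "readout.0", "readout.1", "readout.2", "head")

    def layer_of(self, weight_name: str) -> str:
        for layer in sorted(self.layer_names(), key=len, reverse=True):
            if weight_name.startswith(layer + "."):
                return layer
        raise KeyError(weight_name)

    def set_finetune_flags(self) -> None:
        """Freeze everything except the six designated fine-tune layers."""
        for name in self.layer_names():
            self.trainable_flags[name] = name in FINETUNE_TRAINABLE_LAYERS

    def set_all_trainable(self) -> None:
        for name in self.layer_names():
            self.trainable_flags[name] = True

    def n_trainable_layers(self) -> int:
        return sum(self.trainable_flags.values())

    def copy(self) -> "ModelParams":
        dup = ModelParams.__new__(ModelParams)
        dup.config = self.config
        dup.weights = {k: v.copy() for k, v in self.weights.items()}
        dup.trainable_flags = dict(self.trainable_flags)
        dup.target_mean = self.target_mean
        dup.target_std = self.target_std
        return dup

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: weights, flags, featurization config, version."""
        meta = {"format_version": CHECKPOINT_FORMAT_VERSION,
                "config": self.config.to_dict(),
                "trainable_flags": self.trainable_flags,
                "target_mean": self.target_mean,
                "target_std": self.target_std}
        arrays = dict(self.weights)
        arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @staticmethod
    def load(path) -> "ModelParams":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
            config = GraphConfig.from_dict(meta["config"])
            params = ModelParams(config, seed=0)
            for name in params.weights:
                if name not in npz:
                    raise ValueError(f"checkpoint missing weight array {name!r}")
                arr = npz[name]
                if arr.shape != params.weights[name].shape:
                    raise ValueError(
                        f"checkpoint weight {name!r} has shape {arr.shape}, "
                        f"expected {params.weights[name].shape}")
                params.weights[name] = arr
        params.trainable_flags = {k: bool(v) for k, v in meta["trainable_flags"].items()}
        params.target_mean = float(meta["target_mean"])
        params.target_std = float(meta["target_std"])
        return params


# ---------------------------------------------------------------------------
# forward pass

def forward(params: ModelParams, graph: FeaturizedGraph,
            tensors: dict[str, "ad.Tensor"] | None = None) -> "ad.Tensor":
    """Run the network; returns an (N, 1) tensor of per-node shifts in ppm.

    ``tensors`` optionally supplies pre-wrapped weight tensors (the training
    loop reuses them so gradients accumulate on the same objects); otherwise
    weights are wrapped read-only.
    """
    if graph.edge_rbf.shape[1] != params.config.n_rbf:
        raise ValueError(
            f"graph has {graph.edge_rbf.shape[1]} RBF features, "
            f"model expects {params.config.n_rbf}")
    t = tensors if tensors is not None else wrap_weights(params, trainable=False)
    src = graph.edge_index[:, 0]
    dst = graph.edge_index[:, 1]
    n = graph.n_nodes

    h0 = ad.gather(t["node_embedding.table"], graph.node_type)
    rbf = ad.Tensor(np.concatenate(
        [graph.edge_rbf, graph.edge_bonded[:, None].astype(float)], axis=1))
    e0 = ad.add(ad.matmul(rbf, t["edge_embedding.W"]), t["edge_embedding.b"])
    edge_in = ad.concat([ad.gather(h0, src), ad.gather(h0, dst), e0], axis=1)
    e1 = ad.relu(ad.add(ad.matmul(edge_in, t["edge_net.0.W"]), t["edge_net.0.b"]))
    e = ad.relu(ad.add(ad.matmul(e1, t["edge_net.1.W"]), t["edge_net.1.b"]))

    h = h0
    for _ in range(params.config.n_passes):
        msg = ad.mul(e, ad.gather(ad.matmul(h, t["mp.msg.W"]), src))
        pooled = ad.scatter_add(msg, dst, n)
        z = ad.sigmoid(ad.add(ad.add(ad.matmul(h, t["mp.gru.Wz"]),
                                     ad.matmul(pooled, t["mp.gru.Uz"])), t["mp.gru.bz"]))
        r = ad.sigmoid(ad.add(ad.add(ad.matmul(h, t["mp.gru.Wr"]),
                                     ad.matmul(pooled, t["mp.gru.Ur"])), t["mp.gru.br"]))
        cand = ad.tanh(ad.add(ad.add(ad.matmul(ad.mul(r, h), t["mp.gru.Wh"]),
                                     ad.matmul(pooled, t["mp.gru.Uh"])), t["mp.gru.bh"]))
        one_minus_z = ad.add_scalar(ad.scale(z, -1.0), 1.0)
        h = ad.add(ad.mul(one_minus_z, h), ad.mul(z, cand))

    x = h
    for k in range(3):
        x = ad.relu(ad.add(ad.matmul(x, t[f"readout.{k}.W"]), t[f"readout.{k}.b"]))
    y = ad.add(ad.matmul(x, t["head.W"]), t["head.b"])
    # de-standardize to ppm
    return ad.add_scalar(ad.scale(y, params.target_std), params.target_mean)


def wrap_weights(params: ModelParams, trainable: bool = True) -> dict[str, "ad.Tensor"]:
    """Wrap weight arrays as tensors; requires_grad follows the per-layer flags."""
    out = {}
    for name, arr in params.weights.items():
        req = trainable and params.trainable_flags[params.layer_of(name)]
        out[name] = ad.Tensor(arr, requires_grad=req)
    return out


def predict_node_shifts(params: ModelParams, graph: FeaturizedGraph) -> np.ndarray:
    """Per-node raw predictions in ppm (no solvent/reference correction)."""
    return forward(params, graph).data[:, 0]


VALID_SOLVENTS = ("water", "methanol", "chloroform", "dmso")
VALID_REFERENCES = ("DSS", "TMS", "TSP")


def predict_shifts(mol: MoleculeRecord, params: ModelParams, solvent: str,
                   reference: str, calibration=None) -> PredictionResult:
    """Predict one shift per hydrogen equivalence group, corrected for
    solvent and reference standard.

    Group shift = mean of member-atom raw predictions, then the linear solvent
    map and the reference offset are applied.  In water, labile groups (H on
    O/N/S) exchange with solvent and are dropped from the output; in the
    organic solvents they are reported.
    """
    from .solvent import CorrectionCalibration  # local import; avoids cycle

    if solvent not in VALID_SOLVENTS:
        raise ValueError(f"unknown solvent {solvent!r}; valid: {list(VALID_SOLVENTS)}")
    if reference not in VALID_REFERENCES:
        raise ValueError(f"unknown reference {reference!r}; valid: {list(VALID_REFERENCES)}")
    calibration = calibration or CorrectionCalibration.identity()
    graph = build_graph(mol, params.config)
    raw = predict_node_shifts(params, graph)
    groups = find_equivalent_hydrogens(mol)
    if solvent == "water":
        groups = [g for g in groups if not g.labile]
    shifts = []
    for g in groups:
        member_mean = float(np.mean([raw[i - 1] for i in sorted(g.member_indices)]))
        shifts.append(calibration.correct(member_mean, solvent, reference))
    return PredictionResult(molecule_id=mol.id, groups=groups, shifts_ppm=shifts,
                            solvent=solvent, reference=reference)
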