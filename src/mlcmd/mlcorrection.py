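"""Localized machine-learned quantum centroid-force correction.

The correction ΔF_c = F_c − F is learned as the negative gradient of a
sum of atomic energies, U_Δ = Σ_a u_{e(a)}(f_a), where f_a is a
rotation-, translation- and permutation-invariant descriptor of atom a's
environment within a cutoff r_c, and u_e is a small feed-forward network
per element.  The descriptor follows the embedded-atom idea: for every
radial Gaussian center r_k and angular order l ≤ L it is the squared
norm of an embedded atomic density,

    f_{a,(k,l)} = Σ_{lx+ly+lz=l} (l!/lx!ly!lz!) [ Σ_{j≠a} c_{e(j)}
                  d_x^{lx} d_y^{ly} d_z^{lz} e^{−α(r−r_k)²} f_cut(r) ]²,

with d = x_j − x_a, f_cut(r) = ½(1+cos πr/r_c).  Squaring makes the
features exactly invariant; the cutoff function makes them C¹ at r_c and
zero for an isolated atom.

Training is pure force matching (fixed-centroid sampling yields forces,
not energies, so the scalar is defined only up to a constant): stage 1
fixes random hidden weights and solves the output layer linearly (extreme
learning machine), stage 2 refines all weights with Levenberg–Marquardt.
Both stages are deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import MolecularConfiguration, minimum_image
from .random import seeded_rng
from .ringpolymer import CentroidForceRecord


# ---------------------------------------------------------------------------
# descriptors


def _angular_components(L: int) -> list[tuple[int, float, tuple[int, int, int]]]:
    """(l, multinomial weight, (lx,ly,lz)) for all l ≤ L."""
    from math import factorial

    comps = []
    for l in range(L + 1):
        for lx in range(l, -1, -1):
            for ly in range(l - lx, -1, -1):
                lz = l - lx - ly
                w = factorial(l) / (factorial(lx) * factorial(ly) * factorial(lz))
                comps.append((l, float(w), (lx, ly, lz)))
    return comps


@dataclass
class DescriptorParams:
    """Hyperparameters of the atomic-environment descriptor."""

    cutoff: float = 4.0  # Å
    L: int = 2  # max angular order
    n_radial: int = 11  # Gaussian-type orbitals along r
    alpha: float | None = None  # Gaussian width parameter, 1/Å²
    element_coeffs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.alpha is None:
            # widths overlapping adjacent centers
            spacing = self.cutoff / max(self.n_radial - 1, 1)
            self.alpha = 1.0 / (2.0 * spacing**2)

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(0.0, self.cutoff, self.n_radial)

    @property
    def n_features(self) -> int:
        return self.n_radial * (self.L + 1)

    def coeff(self, elem: str) -> float:
        if elem not in self.element_coeffs:
            # deterministic distinct default per element
            self.element_coeffs[elem] = 1.0 + 0.5 * len(self.element_coeffs)
        return self.element_coeffs[elem]


def _cutoff_fn(r: np.ndarray, rc: float) -> tuple[np.ndarray, np.ndarray]:
    """½(1+cos πr/rc) and its derivative; both vanish at rc."""
    x = np.pi * r / rc
    f = 0.5 * (1.0 + np.cos(x))
    df = -0.5 * np.pi / rc * np.sin(x)
    return f, df


def _pair_terms(
    config: MolecularConfiguration,
    params: DescriptorParams,
    with_gradients: bool = False,
):
    """Vectorized descriptor core.

    Returns ``(feats, idx_a, idx_j, grad_pair)`` where ``feats`` is
    (N, nf); ``idx_a``/``idx_j`` list every (center, neighbor) pair within
    the cutoff and ``grad_pair[p] = ∂f_{idx_a[p]}/∂x_{idx_j[p]}`` with
    shape (3, nf) (``None`` unless gradients requested).  The self term
    is ∂f_a/∂x_a = −Σ_j grad_pair over the pairs centered on a.
    """
    N = config.n_atoms
    nf = params.n_features
    K = params.n_radial
    comps = _angular_components(params.L)
    centers = params.centers
    rc = params.cutoff
    cell = config.cell if config.periodic else None
    if cell is not None and rc > min(cell) / 2:
        raise ValueError("descriptor cutoff exceeds half the shortest box length")
    coeffs = np.array([params.coeff(e) for e in config.elements])

    pos = config.positions
    d = pos[None, :, :] - pos[:, None, :]  # d[a, j] = x_j − x_a
    d = minimum_image(d, cell)
    r2 = np.sum(d**2, axis=-1)
    mask = (r2 < rc * rc) & ~np.eye(N, dtype=bool)
    idx_a, idx_j = np.where(mask)
    feats = np.zeros((N, nf))
    if idx_a.size == 0:
        return feats, idx_a, idx_j, (np.zeros((0, 3, nf)) if with_gradients else None)
    dv = d[idx_a, idx_j]  # (Np, 3)
    rv = np.sqrt(r2[idx_a, idx_j])
    if np.any(rv < 1e-8):
        raise ValueError("coincident atoms within the descriptor cutoff (r < 1e-8 Å)")
    fc, dfc = _cutoff_fn(rv, rc)
    c = coeffs[idx_j]
    gauss = np.exp(-params.alpha * (rv[:, None] - centers[None, :]) ** 2)
    g = c[:, None] * gauss * fc[:, None]  # (Np, K)
    if with_gradients:
        dg_dr = c[:, None] * (
            -2.0 * params.alpha * (rv[:, None] - centers[None, :]) * gauss * fc[:, None]
            + gauss * dfc[:, None]
        )
        rhat = dv / rv[:, None]
        grad_pair = np.zeros((idx_a.size, 3, nf))
    else:
        grad_pair = None

    n_comps = len(comps)
    T_all = np.empty((n_comps, idx_a.size))
    Ssum_all = np.zeros((n_comps, N, K))
    for ci, (l, w, (lx, ly, lz)) in enumerate(comps):
        T = dv[:, 0] ** lx * dv[:, 1] ** ly * dv[:, 2] ** lz
        T_all[ci] = T
        np.add.at(Ssum_all[ci], idx_a, T[:, None] * g)
        sl = slice(l * K, (l + 1) * K)
        feats[:, sl] += w * Ssum_all[ci] ** 2
    if with_gradients:
        for ci, (l, w, (lx, ly, lz)) in enumerate(comps):
            T = T_all[ci]
            gradT = np.zeros((idx_a.size, 3))
            if lx:
                gradT[:, 0] = lx * dv[:, 0] ** (lx - 1) * dv[:, 1] ** ly * dv[:, 2] ** lz
            if ly:
                gradT[:, 1] = ly * dv[:, 0] ** lx * dv[:, 1] ** (ly - 1) * dv[:, 2] ** lz
            if lz:
                gradT[:, 2] = lz * dv[:, 0] ** lx * dv[:, 1] ** ly * dv[:, 2] ** (lz - 1)
            # ∂S_pair/∂x_j = ∇T·g + T·(dg/dr)·r̂   (Np, 3, K)
            dS = gradT[:, :, None] * g[:, None, :] \
                + (T[:, None] * dg_dr)[:, None, :] * rhat[:, :, None]
            sl = slice(l * K, (l + 1) * K)
            grad_pair[:, :, sl] += 2.0 * w * Ssum_all[ci][idx_a][:, None, :] * dS
    return feats, idx_a, idx_j, grad_pair


def compute_features(
    config: MolecularConfiguration,
    params: DescriptorParams,
    with_gradients: bool = False,
):
    """Per-atom descriptor vectors (N, n_features).

    With ``with_gradients`` also returns, per atom a, the pair
    ``(indices, grad)`` where ``grad[i]`` is ∂f_a/∂x_{indices[i]} with
    shape (n_idx, 3, n_features); the atom itself is the last index.
    """
    feats, idx_a, idx_j, grad_pair = _pair_terms(config, params, with_gradients)
    if not with_gradients:
        return feats
    N = config.n_atoms
    nf = params.n_features
    grads: list[tuple[np.ndarray, np.ndarray]] = []
    order = np.argsort(idx_a, kind="stable")
    bounds = np.searchsorted(idx_a[order], np.arange(N + 1))
    for a in range(N):
        sel = order[bounds[a] : bounds[a + 1]]
        nbr = idx_j[sel]
        ga = np.empty((nbr.size + 1, 3, nf))
        ga[:-1] = grad_pair[sel]
        ga[-1] = -grad_pair[sel].sum(axis=0) if nbr.size else 0.0
        grads.append((np.concatenate([nbr, [a]]), ga))
    return feats, grads


# ---------------------------------------------------------------------------
# per-element networks


def _net_shapes(n_in: int, hidden: tuple[int, ...]) -> list[tuple[int, ...]]:
    shapes = []
    prev = n_in
    for h in hidden:
        shapes += [(h, prev), (h,)]
        prev = h
    shapes += [(prev,)]  # output weights; output bias omitted (forces only)
    return shapes


class ElementNet:
    """tanh MLP u(f): hidden layers + linear scalar output (no output bias)."""

    def __init__(self, n_in: int, hidden: tuple[int, ...] = (20, 20)):
        self.n_in = n_in
        self.hidden = tuple(hidden)
        self.shapes = _net_shapes(n_in, self.hidden)
        self.params = [np.zeros(s) for s in self.shapes]

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(s)) for s in self.shapes)

    def get_flat(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.params])

    def set_flat(self, flat: np.ndarray) -> None:
        i = 0
        for j, s in enumerate(self.shapes):
            n = int(np.prod(s))
            self.params[j] = flat[i : i + n].reshape(s)
            i += n

    def init_random(self, rng: np.random.Generator) -> None:
        prev = self.n_in
        k = 0
        for h in self.hidden:
            self.params[k] = rng.standard_normal((h, prev)) / np.sqrt(prev)
            self.params[k + 1] = rng.standard_normal(h) * 0.1
            prev = h
            k += 2
        self.params[k] = rng.standard_normal(prev) / np.sqrt(prev)

    def value_and_grad(self, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """u (n,) and du/df (n, n_in) for a batch of feature rows."""
        h = F
        hs = []
        k = 0
        for _ in self.hidden:
            W, b = self.params[k], self.params[k + 1]
            z = h @ W.T + b
            h = np.tanh(z)
            hs.append(h)
            k += 2
        w_out = self.params[k]
        u = h @ w_out
        # backward: du/df
        g = np.broadcast_to(w_out, h.shape).copy()  # (n, h_last)
        for layer in range(len(self.hidden) - 1, -1, -1):
            W = self.params[2 * layer]
            g = (g * (1.0 - hs[layer] ** 2)) @ W
        return u, g


# ---------------------------------------------------------------------------
# the correction model


@dataclass
class CorrectionModel:
    """Per-element networks whose scalar-sum negative gradient is ΔF_c."""

    params: DescriptorParams
    elements: list[str]
    nets: dict[str, ElementNet]
    feat_shift: np.ndarray  # (n_features,)
    feat_scale: np.ndarray  # (n_features,)
    metadata: dict = field(default_factory=dict)

    @classmethod
    def create(
        cls,
        elements: list[str],
        params: DescriptorParams | None = None,
        hidden: tuple[int, ...] = (20, 20),
        seed: int | np.random.Generator = 0,
    ) -> "CorrectionModel":
        params = params or DescriptorParams()
        rng = seeded_rng(seed)
        nets = {}
        for e in sorted(set(elements)):
            net = ElementNet(params.n_features, hidden)
            net.init_random(rng)
            nets[e] = net
        nf = params.n_features
        return cls(
            params=params,
            elements=sorted(set(elements)),
            nets=nets,
            feat_shift=np.zeros(nf),
            feat_scale=np.ones(nf),
            metadata={},
        )

    # -- prediction ------------------------------------------------------
    def _check_elements(self, config: MolecularConfiguration) -> None:
        unknown = set(config.elements) - set(self.elements)
        if unknown:
            raise KeyError(f"model has no network for element(s) {sorted(unknown)}")

    def _atom_gradients(self, feats: np.ndarray, elements: list[str]) -> np.ndarray:
        """du/df per atom in raw-feature space, (N, n_features)."""
        g = np.zeros_like(feats)
        fn = (feats - self.feat_shift) / self.feat_scale
        for e in set(elements):
            idx = [i for i, el in enumerate(elements) if el == e]
            _, ge = self.nets[e].value_and_grad(fn[idx])
            g[idx] = ge / self.feat_scale
        return g

    def predict_delta_forces(self, config: MolecularConfiguration) -> np.ndarray:
        """Conservative correction forces ΔF (N, 3) in kJ/mol/Å."""
        self._check_elements(config)
        feats, idx_a, idx_j, grad_pair = _pair_terms(
            config, self.params, with_gradients=True
        )
        g = self._atom_gradients(feats, config.elements)
        forces = np.zeros((config.n_atoms, 3))
        if idx_a.size:
            # F_i = −Σ_a (∂f_a/∂x_i)·g_a ; pair term hits the neighbor,
            # the equal-and-opposite self term hits the center
            contrib = np.einsum("pkf,pf->pk", grad_pair, g[idx_a])
            np.add.at(forces, idx_j, -contrib)
            np.add.at(forces, idx_a, contrib)
        return forces

    def energy(self, config: MolecularConfiguration) -> float:
        """The model scalar Σ_a u_a (defined up to a constant)."""
        self._check_elements(config)
        feats = compute_features(config, self.params)
        fn = (feats - self.feat_shift) / self.feat_scale
        total = 0.0
        for e in set(config.elements):
            idx = [i for i, el in enumerate(config.elements) if el == e]
            u, _ = self.nets[e].value_and_grad(fn[idx])
            total += float(u.sum())
        return total

    # -- (de)serialization ------------------------------------------------
    def save(self, path: str | Path) -> None:
        blob = {
            "schema": 1,
            "descriptor": {
                "cutoff": self.params.cutoff,
                "L": self.params.L,
                "n_radial": self.params.n_radial,
                "alpha": self.params.alpha,
                "element_coeffs": self.params.element_coeffs,
            },
            "elements": self.elements,
            "hidden": list(next(iter(self.nets.values())).hidden),
            "weights": {e: net.get_flat().tolist() for e, net in self.nets.items()},
            "feat_shift": self.feat_shift.tolist(),
            "feat_scale": self.feat_scale.tolist(),
            "metadata": {
                k: v for k, v in self.metadata.items()
                if isinstance(v, (int, float, str, bool, list))
            },
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "CorrectionModel":
        blob = json.loads(Path(path).read_text())
        d = blob["descriptor"]
        params = DescriptorParams(
            cutoff=d["cutoff"], L=d["L"], n_radial=d["n_radial"], alpha=d["alpha"],
            element_coeffs=dict(d["element_coeffs"]),
        )
        model = cls.create(blob["elements"], params, hidden=tuple(blob["hidden"]))
        for e, w in blob["weights"].items():
            model.nets[e].set_flat(np.array(w))
        model.feat_shift = np.array(blob["feat_shift"])
        model.feat_scale = np.array(blob["feat_scale"])
        model.metadata = blob.get("metadata", {})
        return model


# ---------------------------------------------------------------------------
# training (force matching, ELM init + Levenberg–Marquardt)


@dataclass
class _Dataset:
    configs: list[MolecularConfiguration]
    labels: list[np.ndarray]  # (N, 3) each
    feats: list[np.ndarray]
    grads: list[list[tuple[np.ndarray, np.ndarray]]]


def _prepare(records, params: DescriptorParams) -> _Dataset:
    configs, labels, feats, grads = [], [], [], []
    for rec in records:
        if isinstance(rec, CentroidForceRecord):
            cfg, lab = rec.centroid, rec.delta_force
        else:
            cfg, lab = rec  # (config, labels) pair
        f, g = compute_features(cfg, params, with_gradients=True)
        configs.append(cfg)
        labels.append(np.asarray(lab, dtype=float))
        feats.append(f)
        grads.append(g)
    return _Dataset(configs, labels, feats, grads)


class _TrainContext:
    """Precomputed force-assembly structure.

    Predicted forces are linear in the per-atom feature gradients g_a =
    ∂u/∂f(f_a): F = −M·g with M built once from the descriptor position
    gradients.  The feature scaler is folded into M so the network only
    ever sees normalized features.
    """

    def __init__(self, ds: _Dataset, model: CorrectionModel):
        self.ds = ds
        nf = model.params.n_features
        self.M = []  # per config: (3N, N, nf)
        offsets = [0]
        for cfg, g in zip(ds.configs, ds.grads):
            N = cfg.n_atoms
            M = np.zeros((3 * N, N, nf))
            for a, (idx, ga) in enumerate(g):
                for i, atom in enumerate(idx):
                    M[3 * atom : 3 * atom + 3, a, :] += ga[i]
            M /= model.feat_scale[None, None, :]
            self.M.append(M)
            offsets.append(offsets[-1] + 3 * N)
        self.offsets = offsets
        self.n_res = offsets[-1]
        # atoms grouped by element across the whole dataset
        self.elem_atoms: dict[str, list[tuple[int, int]]] = {e: [] for e in model.elements}
        for ci, cfg in enumerate(ds.configs):
            for a, e in enumerate(cfg.elements):
                self.elem_atoms[e].append((ci, a))
        self.fn: dict[str, np.ndarray] = {}
        for e, pairs in self.elem_atoms.items():
            if pairs:
                rows = np.array([ds.feats[ci][a] for ci, a in pairs])
                self.fn[e] = (rows - model.feat_shift) / model.feat_scale
            else:
                self.fn[e] = np.zeros((0, nf))
        self.y = np.concatenate([lab.ravel() for lab in ds.labels])

    def predict(self, model: CorrectionModel) -> np.ndarray:
        nf = model.params.n_features
        G = [np.zeros((cfg.n_atoms, nf)) for cfg in self.ds.configs]
        for e in model.elements:
            pairs = self.elem_atoms[e]
            if not pairs:
                continue
            _, g = model.nets[e].value_and_grad(self.fn[e])
            for (ci, a), row in zip(pairs, g):
                G[ci][a] = row
        out = np.empty(self.n_res)
        for ci, M in enumerate(self.M):
            out[self.offsets[ci] : self.offsets[ci + 1]] = -np.einsum(
                "knf,nf->k", M, G[ci]
            )
        return out


def _get_all_flat(model: CorrectionModel) -> np.ndarray:
    return np.concatenate([model.nets[e].get_flat() for e in model.elements])


def _set_all_flat(model: CorrectionModel, flat: np.ndarray) -> None:
    i = 0
    for e in model.elements:
        n = model.nets[e].n_params
        model.nets[e].set_flat(flat[i : i + n])
        i += n


def _elm_solve(model: CorrectionModel, ctx: _TrainContext, ridge: float = 1e-8) -> None:
    """Stage 1: with hidden weights fixed, predicted forces are linear in
    the output-layer weights; solve the joint least-squares problem."""
    cols = []
    col_meta = []
    for e in model.elements:
        net = model.nets[e]
        pairs = ctx.elem_atoms[e]
        h = ctx.fn[e]
        n_a = h.shape[0]
        if net.hidden:
            h_last = net.hidden[-1]
            # forward pass through hidden layers for all atoms of this element
            hs = []
            k = 0
            for _ in net.hidden:
                W, b = net.params[k], net.params[k + 1]
                h = np.tanh(h @ W.T + b)
                hs.append(h)
                k += 2
            # ∂h_last[u]/∂f for every unit u at once: batched backprop of I
            gg = np.broadcast_to(np.eye(h_last), (n_a, h_last, h_last)).copy()
            for layer in range(len(net.hidden) - 1, -1, -1):
                W = net.params[2 * layer]
                gg = (gg * (1.0 - hs[layer] ** 2)[:, None, :]) @ W
        else:
            # linear readout: the "units" are the features themselves
            h_last = net.n_in
            gg = np.broadcast_to(np.eye(h_last), (n_a, h_last, h_last)).copy()
        # gg: (n_a, h_last, nf) in normalized-feature space
        for u in range(h_last):
            col = np.zeros(ctx.n_res)
            Gu = [None] * len(ctx.ds.configs)
            for (ci, a), row in zip(pairs, gg[:, u, :]):
                if Gu[ci] is None:
                    Gu[ci] = np.zeros((ctx.ds.configs[ci].n_atoms, row.size))
                Gu[ci][a] = row
            for ci, M in enumerate(ctx.M):
                if Gu[ci] is not None:
                    col[ctx.offsets[ci] : ctx.offsets[ci + 1]] = -np.einsum(
                        "knf,nf->k", M, Gu[ci]
                    )
            cols.append(col)
            col_meta.append((e, u))
    A = np.column_stack(cols)
    AtA = A.T @ A + ridge * np.eye(A.shape[1])
    w = np.linalg.solve(AtA, A.T @ ctx.y)
    for (e, u), wv in zip(col_meta, w):
        model.nets[e].params[-1][u] = wv


def train(
    records,
    params: DescriptorParams | None = None,
    hidden: tuple[int, ...] = (20, 20),
    seed: int = 0,
    loss_threshold: float = 0.1,
    max_lm_iters: int = 60,
    fd_step: float = 1e-6,
    verbose: bool = False,
) -> CorrectionModel:
    """Train a correction model on ΔF_c labels by force matching.

    ``records`` is an iterable of :class:`CentroidForceRecord` or of
    ``(configuration, labels)`` pairs.  The loss is the RMS force residual
    in kJ/mol/Å; optimization stops when it falls below
    ``loss_threshold`` (default 0.1) or the LM iteration budget is spent.
    Deterministic for a fixed seed.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least two training records")
    params = params or DescriptorParams()
    ds = _prepare(records, params)
    elements = sorted({e for cfg in ds.configs for e in cfg.elements})
    model = CorrectionModel.create(elements, params, hidden=hidden, seed=seed)
    # feature normalization from the training set
    allf = np.vstack(ds.feats)
    model.feat_shift = allf.mean(axis=0)
    scale = allf.std(axis=0)
    model.feat_scale = np.where(scale > 1e-12, scale, 1.0)

    ctx = _TrainContext(ds, model)
    y = ctx.y
    _elm_solve(model, ctx)
    r = ctx.predict(model) - y
    loss_trace = [float(np.sqrt(np.mean(r**2)))]
    if verbose:
        print(f"ELM loss: {loss_trace[-1]:.6g}")

    lam = 1e-3
    w = _get_all_flat(model)
    best_w, best_loss = w.copy(), loss_trace[-1]
    n_par = w.size
    for it in range(max_lm_iters):
        if loss_trace[-1] <= loss_threshold:
            break
        # finite-difference Jacobian of the residual vector
        J = np.empty((y.size, n_par))
        for p in range(n_par):
            wp = w.copy()
            wp[p] += fd_step
            _set_all_flat(model, wp)
            rp = ctx.predict(model)
            wp[p] -= 2 * fd_step
            _set_all_flat(model, wp)
            rm = ctx.predict(model)
            J[:, p] = (rp - rm) / (2 * fd_step)
        _set_all_flat(model, w)
        g = J.T @ r
        H = J.T @ J
        accepted = False
        for _ in range(12):
            try:
                delta = np.linalg.solve(H + lam * np.diag(np.maximum(np.diag(H), 1e-12)), -g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            w_try = w + delta
            _set_all_flat(model, w_try)
            r_try = ctx.predict(model) - y
            loss_try = float(np.sqrt(np.mean(r_try**2)))
            if loss_try < loss_trace[-1]:
                w, r = w_try, r_try
                loss_trace.append(loss_try)
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                break
            lam *= 10
        if verbose:
            print(f"LM iter {it}: loss {loss_trace[-1]:.6g} lam {lam:.2g}")
        if accepted and loss_trace[-1] < best_loss:
            best_loss = loss_trace[-1]
            best_w = w.copy()
        if not accepted:
            break
        if len(loss_trace) > 2 and abs(loss_trace[-2] - loss_trace[-1]) < 1e-12 * max(loss_trace[-1], 1e-30):
            break
    _set_all_flat(model, best_w)
    model.metadata = {
        "loss_trace": [float(v) for v in loss_trace],
        "final_loss": float(best_loss),
        "converged": bool(best_loss <= loss_threshold),
        "seed": int(seed),
        "n_records": len(records),
        "loss_threshold": loss_threshold,
    }
    return model


def predict_delta_forces(model: CorrectionModel, config: MolecularConfiguration) -> np.ndarray:
    """Module-level alias for :meth:`CorrectionModel.predict_delta_forces`."""
    return model.predict_delta_forces(config)
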