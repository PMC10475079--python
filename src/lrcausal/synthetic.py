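"""Synthetic fixtures: staged embryo-like matrices with planted causal structure.

Three generators cover every testing need without any external download:

* :func:`simulate_var_pair` — a bivariate vector autoregression with known
  (theoretical) Granger causality, for calibration and power studies.
* :func:`simulate_embryo` — one lineage of stage-labelled cells along a true
  pseudotime, with smooth TF cluster programs (Gaussian-bump archetypes plus
  AR(1) innovations), TF-driven target genes, and planted LR pairs whose
  interaction-score dynamics are lag-coupled to a designated TF cluster in a
  configured direction (forward: LR drives the cluster; backward: the
  cluster drives LR; feedback: both).
* :func:`simulate_two_lineages` — sender/receiver lineages of deliberately
  unequal cell number sharing a latent time axis, with planted
  ligand -> receptor -> TF -> ligand feedback motifs, for the paracrine
  workflow.

All values live in log-expression space (coupling injected there, matrices
shifted to be non-negative).  A single integer seed drives named sub-streams
with fixed offsets, so adding a component never shifts existing draws and
identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CellMetadata, ExpressionMatrix, LRPair, OrderedSeries

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_var_pair",
    "simulate_embryo",
    "simulate_two_lineages",
    "default_planted",
]

# fixed sub-stream offsets (never reordered; see module docstring)
_STREAMS = {
    "time": 11,
    "clusters": 23,
    "tfs": 37,
    "targets": 41,
    "pairs": 53,
    "noise": 67,
    "dropout": 71,
    "sender": 83,
    "receiver": 89,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[component]])


def default_planted(n: int = 8) -> list[str]:
    """A forward/backward/feedback mix for n planted pairs."""
    cycle = ["feedback", "backward", "forward"]
    return [cycle[i % 3] for i in range(n)]


@dataclass
class SimulationConfig:
    """Stated world for the embryo-like generators.

    Defaults describe a small Smart-seq-style trajectory: 200 cells over 6
    named stages, 500 genes of which 30 are TFs (5 per temporal cluster),
    60 LR pairs with 8 planted causal pairs at lag-1 coupling 0.8, cell-level
    log-expression noise sd 0.2 and no dropout (droplet-style sparsity is
    opted into via ``dropout_rate``).
    """

    n_cells: int = 200
    n_stages: int = 6
    n_genes: int = 500
    n_lr_pairs: int = 60
    planted: list[str] = field(default_factory=default_planted)
    coupling: float = 0.8
    noise_sd: float = 0.2
    dropout_rate: float = 0.0
    lag_true: int = 1
    seed: int = 0
    n_tf_clusters: int = 6
    tfs_per_cluster: int = 5
    targets_per_tf: int = 8

    def __post_init__(self) -> None:
        if self.n_cells < 10 * self.n_stages:
            raise ValueError("need at least 10 cells per stage")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.noise_sd < 0 or self.coupling < 0:
            raise ValueError("noise_sd and coupling must be >= 0")
        if len(self.planted) > self.n_lr_pairs:
            raise ValueError("more planted classes than LR pairs")
        bad = set(self.planted) - {"forward", "backward", "feedback", "none"}
        if bad:
            raise ValueError(f"unknown planted classes: {bad}")

    @property
    def n_tfs(self) -> int:
        return self.n_tf_clusters * self.tfs_per_cluster


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside every simulated dataset."""

    true_pseudotime: pd.Series
    pair_class: dict[LRPair, str]
    regulons: dict[str, set[str]]
    tf_cluster: dict[str, int]


def _check_stationary(a: float, b: float, c_xy: float, c_yx: float) -> None:
    if abs(a) >= 1 or abs(b) >= 1:
        raise ValueError("AR coefficients must have modulus < 1")
    # companion matrix of the lag-1 VAR part
    A = np.array([[a, c_yx], [c_xy, b]])
    if np.max(np.abs(np.linalg.eigvals(A))) >= 1:
        raise ValueError("VAR parameters are non-stationary")


def simulate_var_pair(
    n: int,
    coupling: float,
    direction: str = "x->y",
    lag_true: int = 1,
    seed: int = 0,
    ar: tuple[float, float] = (0.5, 0.5),
    noise_sd: float = 1.0,
    burn_in: int = 100,
) -> tuple[OrderedSeries, OrderedSeries]:
    """Bivariate VAR with theoretical Granger causality equal to ``direction``.

    ``x_t = a x_{t-1} (+ c y_{t-lag}) + eps``, ``y_t = b y_{t-1}
    (+ c x_{t-lag}) + eta``; the coupling terms are present per
    ``direction`` in {"none", "x->y", "y->x", "feedback"}.  The first
    ``burn_in`` steps are discarded.
    """
    if direction not in ("none", "x->y", "y->x", "feedback"):
        raise ValueError(f"unknown direction {direction!r}")
    if lag_true < 1:
        raise ValueError("lag_true must be >= 1")
    a, b = ar
    c_xy = coupling if direction in ("x->y", "feedback") else 0.0
    c_yx = coupling if direction in ("y->x", "feedback") else 0.0
    _check_stationary(a, b, c_xy, c_yx)
    rng = np.random.default_rng([int(seed), 101])
    total = n + burn_in
    x = np.zeros(total)
    y = np.zeros(total)
    ex = rng.normal(0, noise_sd, total)
    ey = rng.normal(0, noise_sd, total)
    for t in range(1, total):
        tl = max(t - lag_true, 0)
        x[t] = a * x[t - 1] + c_yx * y[tl] + ex[t]
        y[t] = b * y[t - 1] + c_xy * x[tl] + ey[t]
    pos = np.arange(n, dtype=float)
    return (
        OrderedSeries(pos, x[burn_in:], label="x"),
        OrderedSeries(pos, y[burn_in:], label="y"),
    )


def _chain_radius(a: float, c: float, lag: int) -> float:
    """Spectral radius of the ligand->receptor->TF->ligand VAR companion matrix."""
    dim = 3 * lag
    A = np.zeros((dim, dim))
    for v in range(3):
        A[v, v] = a                      # own lag-1 terms
    src = {0: 2, 1: 0, 2: 1}             # lambda<-tau, rho<-lambda, tau<-rho
    for v, u in src.items():
        A[v, (lag - 1) * 3 + u] = c      # coupling at the configured lag
    for j in range(lag - 1):             # shift register for deeper lags
        for v in range(3):
            A[3 * (j + 1) + v, 3 * j + v] = 1.0
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def _stationary_chain_coupling(a: float, c: float, lag: int, target: float = 0.95) -> float:
    """Largest coupling <= c keeping the feedback chain's radius below ~0.97."""
    if c <= 0 or _chain_radius(a, c, lag) < 0.97:
        return c
    lo, hi = 0.0, c
    for _ in range(60):
        mid = (lo + hi) / 2
        if _chain_radius(a, mid, lag) < target:
            lo = mid
        else:
            hi = mid
    return lo


def _archetype(t: np.ndarray, center: float, width: float = 0.15, amp: float = 2.0) -> np.ndarray:
    return amp * np.exp(-((t - center) ** 2) / (2 * width**2))


def _ar1(rng: np.random.Generator, n: int, a: float = 0.6, sd: float = 0.5) -> np.ndarray:
    e = rng.normal(0, sd, n)
    z = np.zeros(n)
    for t in range(1, n):
        z[t] = a * z[t - 1] + e[t]
    return z


def _shift_nonneg(v: np.ndarray) -> np.ndarray:
    return v - v.min()


def simulate_embryo(
    config: SimulationConfig | None = None,
) -> tuple[ExpressionMatrix, CellMetadata, list[LRPair], list[str], SimulationTruth]:
    """One-lineage staged dataset with planted LR<->TF-cluster causal structure.

    Cells sit at sorted uniform positions on [0, 1] (true pseudotime), binned
    into equal-width named stages.  Each TF cluster carries a smooth Gaussian
    archetype plus an AR(1) innovation signal; member TFs observe it with
    iid noise and drive ``targets_per_tf`` target genes each.  Planted LR
    pairs couple their shared latent interaction signal to a designated
    cluster's innovation signal at ``lag_true`` cell steps in the configured
    direction; ligand and receptor genes follow that latent with small
    independent noise, so the pair passes the co-variation screen and its
    interaction score is an affine image of the latent.  Remaining LR genes
    and filler genes are independent noise around gene-specific baselines.
    """
    cfg = config or SimulationConfig()
    n = cfg.n_cells
    t = np.sort(_rng(cfg.seed, "time").uniform(0, 1, n))
    stage_edges = np.linspace(0, 1, cfg.n_stages + 1)
    stage_idx = np.clip(np.searchsorted(stage_edges, t, side="right") - 1, 0, cfg.n_stages - 1)
    stage_order = [f"S{i + 1}" for i in range(cfg.n_stages)]
    cell_ids = [f"cell{str(i).zfill(4)}" for i in range(n)]

    rng_cl = _rng(cfg.seed, "clusters")
    centers = np.linspace(0.08, 0.92, cfg.n_tf_clusters)
    cluster_arch = [_archetype(t, c) for c in centers]
    cluster_innov = [_ar1(rng_cl, n) for _ in range(cfg.n_tf_clusters)]

    # planted LR latents first: forward/feedback couplings feed back into the
    # cluster innovation signals before TFs observe them
    rng_pairs = _rng(cfg.seed, "pairs")
    planted_latent: list[np.ndarray] = []
    planted_cluster: list[int] = []
    for i, klass in enumerate(cfg.planted):
        c = i % cfg.n_tf_clusters
        planted_cluster.append(c)
        s = np.zeros(n)
        e = rng_pairs.normal(0, 0.3, n)
        z = cluster_innov[c]
        lag = cfg.lag_true
        for step in range(1, n):
            drive = cfg.coupling * z[step - lag] if (klass in ("backward", "feedback") and step >= lag) else 0.0
            s[step] = 0.5 * s[step - 1] + drive + e[step]
        if klass in ("forward", "feedback"):
            z_new = np.zeros(n)
            ez = rng_pairs.normal(0, 0.5, n)
            for step in range(1, n):
                drive = cfg.coupling * s[step - lag] if step >= lag else 0.0
                z_new[step] = 0.6 * z_new[step - 1] + drive + ez[step]
            cluster_innov[c] = z_new
            z = z_new
            if klass == "feedback":
                # re-run s against the updated cluster signal to close the loop
                for step in range(1, n):
                    drive = cfg.coupling * z[step - lag] if step >= lag else 0.0
                    s[step] = 0.5 * s[step - 1] + drive + e[step]
        planted_latent.append(s)

    cluster_signal = [cluster_arch[c] + cluster_innov[c] for c in range(cfg.n_tf_clusters)]

    gene_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    rng_tf = _rng(cfg.seed, "tfs")
    tf_list: list[str] = []
    tf_cluster: dict[str, int] = {}
    tf_signal: dict[str, np.ndarray] = {}
    for c in range(cfg.n_tf_clusters):
        for j in range(cfg.tfs_per_cluster):
            name = f"TF{c + 1}_{j + 1}"
            sig = cluster_signal[c] + rng_tf.normal(0, cfg.noise_sd, n)
            tf_list.append(name)
            tf_cluster[name] = c + 1
            tf_signal[name] = sig
            gene_ids.append(name)
            gene_rows.append(_shift_nonneg(sig))

    rng_tg = _rng(cfg.seed, "targets")
    regulons: dict[str, set[str]] = {tf: set() for tf in tf_list}
    for tf in tf_list:
        for j in range(cfg.targets_per_tf):
            name = f"TG_{tf}_{j + 1}"
            sig = 0.8 * tf_signal[tf] + rng_tg.normal(0, cfg.noise_sd * 1.5, n)
            regulons[tf].add(name)
            gene_ids.append(name)
            gene_rows.append(_shift_nonneg(sig))

    lr_pairs = [LRPair(f"Lg{str(i).zfill(3)}", f"Rc{str(i).zfill(3)}") for i in range(cfg.n_lr_pairs)]
    pair_class: dict[LRPair, str] = {}
    for i, pair in enumerate(lr_pairs):
        if i < len(cfg.planted):
            klass = cfg.planted[i]
            s = planted_latent[i]
            lig = s + rng_pairs.normal(0, 0.1 * max(cfg.noise_sd, 0.1), n)
            rec = s + rng_pairs.normal(0, 0.1 * max(cfg.noise_sd, 0.1), n)
        else:
            klass = "none"
            lig = rng_pairs.normal(1.0, max(cfg.noise_sd, 0.05), n)
            rec = rng_pairs.normal(1.0, max(cfg.noise_sd, 0.05), n)
        pair_class[pair] = klass
        gene_ids.extend([pair.ligand, pair.receptor])
        gene_rows.append(_shift_nonneg(lig))
        gene_rows.append(_shift_nonneg(rec))

    rng_noise = _rng(cfg.seed, "noise")
    n_filler = max(cfg.n_genes - len(gene_ids), 0)
    for i in range(n_filler):
        base = rng_noise.uniform(0.2, 2.0)
        gene_ids.append(f"G{str(i).zfill(4)}")
        gene_rows.append(np.clip(rng_noise.normal(base, cfg.noise_sd, n), 0, None))

    values = np.vstack(gene_rows)
    if cfg.dropout_rate > 0:
        mask = _rng(cfg.seed, "dropout").random(values.shape) < cfg.dropout_rate
        values = np.where(mask, 0.0, values)

    mat = ExpressionMatrix(values, gene_ids, cell_ids)
    meta = CellMetadata(
        pd.DataFrame(
            {"stage": [stage_order[i] for i in stage_idx], "pseudotime": t},
            index=cell_ids,
        ),
        stage_order,
    )
    truth = SimulationTruth(
        true_pseudotime=pd.Series(t, index=cell_ids),
        pair_class=pair_class,
        regulons=regulons,
        tf_cluster=tf_cluster,
    )
    return mat, meta, lr_pairs, tf_list, truth


def simulate_two_lineages(
    config: SimulationConfig | None = None,
    n_sender: int = 180,
    n_receiver: int = 260,
    n_true_pairs: int = 5,
    n_grid: int = 40,
):
    """Sender/receiver lineages of unequal size with planted paracrine motifs.

    A latent VAR chain runs on a shared coarse time axis (``n_grid`` steps
    spanning the trajectory, so its dynamics live on timescales the
    interpolation bandwidth can resolve) per true pair: ligand -> receptor
    -> TF, with TF -> ligand feedback closing the loop, so interaction score
    and TF expression are mutually Granger-linked once sampled and
    interpolated.  Latents are linearly interpolated to each cell's
    pseudotime.  Sender cells express the ligand genes, receiver cells the
    receptor and TF genes plus each TF's target program; both lineages also
    carry independent filler genes and a complement of uncoupled ("null")
    LR pairs.  With ``coupling = 0`` the chain terms vanish and every pair
    is null.

    Returns ``(sender, receiver, lr_pairs, tf_list, truth)`` where sender
    and receiver are ``(ExpressionMatrix, CellMetadata)`` bundles.
    """
    cfg = config or SimulationConfig()
    if n_true_pairs > cfg.n_lr_pairs:
        raise ValueError("n_true_pairs exceeds n_lr_pairs")
    rng_s = _rng(cfg.seed, "sender")
    rng_r = _rng(cfg.seed, "receiver")
    grid_t = np.linspace(0, 1, n_grid)
    lag = max(cfg.lag_true, 1) * 2        # latent lag in coarse steps (~0.05 of the axis)
    burn = 50

    t_send = np.sort(rng_s.uniform(0, 1, n_sender))
    t_recv = np.sort(rng_r.uniform(0, 1, n_receiver))

    def _at(latent: np.ndarray, times: np.ndarray) -> np.ndarray:
        return np.interp(times, grid_t, latent)

    lr_pairs = [LRPair(f"Lg{str(i).zfill(3)}", f"Rc{str(i).zfill(3)}") for i in range(cfg.n_lr_pairs)]
    tf_list = [f"MTF{str(i).zfill(2)}" for i in range(max(n_true_pairs, 1) + 5)]

    sender_rows: dict[str, np.ndarray] = {}
    receiver_rows: dict[str, np.ndarray] = {}
    pair_class: dict[LRPair, str] = {}
    regulons: dict[str, set[str]] = {}

    ar_chain = 0.5
    # the closed ligand->receptor->TF->ligand loop is explosive at large gain;
    # cap the per-link coupling so the VAR stays stationary (radius ~0.95)
    c = _stationary_chain_coupling(ar_chain, cfg.coupling, lag)
    arch_centers = np.linspace(0.1, 0.9, len(tf_list))
    for i, pair in enumerate(lr_pairs):
        if i < n_true_pairs and c > 0:
            total = n_grid + burn
            lam = np.zeros(total)
            rho = np.zeros(total)
            tau = np.zeros(total)
            e_l = rng_s.normal(0, 1.0, total)
            e_r = rng_r.normal(0, 0.3, total)
            e_t = rng_r.normal(0, 0.3, total)
            for s in range(1, total):
                sl = max(s - lag, 0)
                lam[s] = ar_chain * lam[s - 1] + c * tau[sl] + e_l[s]
                rho[s] = ar_chain * rho[s - 1] + c * lam[sl] + e_r[s]
                tau[s] = ar_chain * tau[s - 1] + c * rho[sl] + e_t[s]
            lam, rho, tau = lam[burn:], rho[burn:], tau[burn:]
            tf = tf_list[i]
            # shared slow developmental program carried by all three genes;
            # the VAR innovations on top provide the causal directionality
            center = 0.25 + 0.5 * (i / max(n_true_pairs - 1, 1))
            ramp_s = 2.5 / (1.0 + np.exp(-(t_send - center) / 0.1))
            ramp_r = 2.0 / (1.0 + np.exp(-(t_recv - center) / 0.1))
            sender_rows[pair.ligand] = _shift_nonneg(
                _at(lam, t_send) + ramp_s + rng_s.normal(0, cfg.noise_sd, n_sender)
            )
            receiver_rows[pair.receptor] = _shift_nonneg(
                _at(rho, t_recv) + ramp_r + rng_r.normal(0, cfg.noise_sd, n_receiver)
            )
            tf_cells = _at(tau, t_recv) + ramp_r
            receiver_rows[tf] = _shift_nonneg(
                tf_cells + rng_r.normal(0, cfg.noise_sd, n_receiver)
            )
            regulons[tf] = set()
            for j in range(cfg.targets_per_tf):
                tg = f"TG_{tf}_{j + 1}"
                receiver_rows[tg] = _shift_nonneg(
                    0.8 * tf_cells + rng_r.normal(0, cfg.noise_sd * 1.5, n_receiver)
                )
                regulons[tf].add(tg)
            pair_class[pair] = "feedback"
        else:
            sender_rows[pair.ligand] = np.clip(
                rng_s.normal(1.0, max(cfg.noise_sd, 0.05), n_sender), 0, None
            )
            receiver_rows[pair.receptor] = np.clip(
                rng_r.normal(1.0, max(cfg.noise_sd, 0.05), n_receiver), 0, None
            )
            pair_class[pair] = "none"

    # remaining TFs: temporal archetype programs with targets (master-TF pool)
    for j, tf in enumerate(tf_list):
        if tf in receiver_rows:
            continue
        arch = _archetype(grid_t, arch_centers[j], width=0.2, amp=2.0)
        innov = _ar1(rng_r, n_grid, a=0.8, sd=0.3)
        sig_cells = _at(arch + innov, t_recv)
        receiver_rows[tf] = _shift_nonneg(sig_cells + rng_r.normal(0, cfg.noise_sd, n_receiver))
        regulons[tf] = set()
        for k in range(cfg.targets_per_tf):
            tg = f"TG_{tf}_{k + 1}"
            receiver_rows[tg] = _shift_nonneg(
                0.8 * sig_cells + rng_r.normal(0, cfg.noise_sd * 1.5, n_receiver)
            )
            regulons[tf].add(tg)

    for lineage_rows, rng, n_c in ((sender_rows, rng_s, n_sender), (receiver_rows, rng_r, n_receiver)):
        n_filler = max(cfg.n_genes - len(lineage_rows), 0)
        for i in range(n_filler):
            base = rng.uniform(0.2, 2.0)
            lineage_rows[f"G{str(i).zfill(4)}"] = np.clip(rng.normal(base, cfg.noise_sd, n_c), 0, None)

    def _bundle(rows: dict[str, np.ndarray], times: np.ndarray, prefix: str):
        cells = [f"{prefix}{str(i).zfill(4)}" for i in range(len(times))]
        values = np.vstack(list(rows.values()))
        if cfg.dropout_rate > 0:
            mask = _rng(cfg.seed, "dropout").random(values.shape) < cfg.dropout_rate
            values = np.where(mask, 0.0, values)
        stage_edges = np.linspace(0, 1, cfg.n_stages + 1)
        sidx = np.clip(np.searchsorted(stage_edges, times, side="right") - 1, 0, cfg.n_stages - 1)
        stage_order = [f"S{i + 1}" for i in range(cfg.n_stages)]
        mat = ExpressionMatrix(values, list(rows.keys()), cells)
        meta = CellMetadata(
            pd.DataFrame({"stage": [stage_order[i] for i in sidx], "pseudotime": times}, index=cells),
            stage_order,
        )
        return mat, meta

    sender = _bundle(sender_rows, t_send, "send")
    receiver = _bundle(receiver_rows, t_recv, "recv")
    truth = SimulationTruth(
        true_pseudotime=pd.Series(
            np.concatenate([t_send, t_recv]),
            index=sender[0].cell_ids + receiver[0].cell_ids,
        ),
        pair_class=pair_class,
        regulons=regulons,
        tf_cluster={},
    )
    return sender, receiver, lr_pairs, tf_list, truth
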