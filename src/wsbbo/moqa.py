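"""QUBO-surrogate sequence generation (the MOQA-style optimizer loop).

Sequence search is lifted into a binary latent space: a binary-latent
autoencoder maps fixed-length sequences to d-bit codes and back.  A
factorization machine (FM) — a low-rank quadratic model over the latent
bits — is fitted to a scalar acquisition value per evaluated point (a
dense non-domination rank by default, or the hypervolume improvement
over the current Pareto front).  Because an FM
is a quadratic pseudo-Boolean function, maximizing it is exactly a QUBO,
which a simulated-annealing sampler solves; the sampled codes are
decoded into new candidate sequences, evaluated on the three objectives,
and fed back into the surrogate.  A quantum annealer could sample the
same QUBO; the sampler backend is the only thing that would change.

The random-generation baseline (i.i.d. uniform residues at equal
evaluation budget) is provided for reference comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .alphabet import AA20, one_hot_flat
from .enrichment import LabeledDataset
from .ensemble import PredictorEnsemble
from .objectives import ObjectiveVector, SolubilityScorer, evaluate
from .pareto import ParetoArchive, dominates

logger = logging.getLogger(__name__)

__all__ = [
    "AutoencoderConfig", "BinaryAutoencoder", "train_autoencoder",
    "FactorizationMachine", "fit_fm", "QUBO", "fm_to_qubo", "anneal_sample",
    "acquisition", "RunState", "moqa_run", "random_generate", "merge_runs",
]


# --------------------------------------------------------------------------
# Binary-latent autoencoder
# --------------------------------------------------------------------------

@dataclass
class AutoencoderConfig:
    epochs: int = 400
    learning_rate: float = 0.05
    seed: int = 0


class BinaryAutoencoder:
    """Linear encoder/decoder pair with a d-bit binary latent code.

    Training uses a straight-through estimator: the forward pass
    thresholds the encoder's sigmoid activations at 0.5, the backward
    pass treats the threshold as identity.  At generation time encoding
    (threshold at 0.5) and decoding (per-position argmax over residue
    logits, lexicographic tie-break via alphabet order) are
    deterministic functions.
    """

    def __init__(self, latent_dim: int, sequence_length: int, alphabet: str = AA20,
                 config: AutoencoderConfig | None = None):
        self.latent_dim = latent_dim
        self.sequence_length = sequence_length
        self.alphabet = alphabet
        self.config = config or AutoencoderConfig()
        n_in = sequence_length * len(alphabet)
        rng = np.random.default_rng(self.config.seed)
        self.We = rng.normal(0, 1.0 / np.sqrt(n_in), (n_in, latent_dim))
        self.be = np.zeros(latent_dim)
        self.Wd = rng.normal(0, 1.0 / np.sqrt(latent_dim), (latent_dim, n_in))
        self.bd = np.zeros(n_in)
        self.train_identity_rate: float | None = None

    # -- deterministic generation-time maps --------------------------------
    def encode(self, sequence: str) -> np.ndarray:
        x = one_hot_flat([sequence], self.alphabet)[0]
        return (x @ self.We + self.be > 0).astype(np.int8)

    def decode(self, bits: np.ndarray) -> str:
        bits = np.asarray(bits, dtype=float)
        if bits.shape != (self.latent_dim,):
            raise ValueError(f"latent vector must have shape ({self.latent_dim},)")
        logits = (bits @ self.Wd + self.bd).reshape(
            self.sequence_length, len(self.alphabet)
        )
        return "".join(self.alphabet[i] for i in logits.argmax(axis=1))

    # -- training -----------------------------------------------------------
    def fit(self, sequences: list[str]) -> "BinaryAutoencoder":
        X = one_hot_flat(sequences, self.alphabet)
        n, L, A = len(sequences), self.sequence_length, len(self.alphabet)
        targets = X.reshape(n, L, A).argmax(axis=2)
        lr = self.config.learning_rate
        params = [self.We, self.be, self.Wd, self.bd]
        opt = _Adam(params, lr)
        for _ in range(self.config.epochs):
            z = _sigmoid(X @ self.We + self.be)
            b = (z > 0.5).astype(float)
            logits = (b @ self.Wd + self.bd).reshape(n, L, A)
            logits -= logits.max(axis=2, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=2, keepdims=True)
            dlogit = p.copy()
            dlogit[np.arange(n)[:, None], np.arange(L)[None, :], targets] -= 1.0
            dlogit /= n * L
            dflat = dlogit.reshape(n, L * A)
            gWd = b.T @ dflat
            gbd = dflat.sum(axis=0)
            db = dflat @ self.Wd.T
            dzlog = db * z * (1 - z)          # straight-through estimator
            gWe = X.T @ dzlog
            gbe = dzlog.sum(axis=0)
            opt.step([gWe, gbe, gWd, gbd])
        recon = [self.decode(self.encode(s)) for s in sequences]
        self.train_identity_rate = float(
            np.mean([r == s for r, s in zip(recon, sequences)])
        )
        logger.info("autoencoder round-trip identity rate: %.3f",
                    self.train_identity_rate)
        return self


def train_autoencoder(sequences: list[str], d: int,
                      config: AutoencoderConfig | None = None,
                      alphabet: str = AA20) -> BinaryAutoencoder:
    """Train a binary autoencoder on uniform-length sequences (n >= 50)."""
    if len(sequences) < 50:
        raise ValueError("need at least 50 sequences to train the autoencoder")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"mixed sequence lengths {sorted(lengths)}")
    model = BinaryAutoencoder(d, lengths.pop(), alphabet, config)
    return model.fit(sequences)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.params, self.lr, self.b1, self.b2, self.eps = params, lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / (1 - self.b1 ** self.t)) / (
                np.sqrt(v / (1 - self.b2 ** self.t)) + self.eps
            )


# --------------------------------------------------------------------------
# Factorization machine surrogate
# --------------------------------------------------------------------------

@dataclass
class FactorizationMachine:
    """Quadratic surrogate y(x) = w0 + sum_i w_i x_i + sum_{i<j} <v_i,v_j> x_i x_j."""

    w0: float
    w: np.ndarray          # (d,)
    V: np.ndarray          # (d, r)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        XV = X @ self.V
        # for binary x, x^2 = x, but keep the general identity
        pair = 0.5 * ((XV ** 2).sum(axis=1) - ((X ** 2) @ (self.V ** 2)).sum(axis=1))
        return self.w0 + X @ self.w + pair


def fit_fm(X: np.ndarray, y: np.ndarray, rank: int = 8, lam: float = 1e-3,
           seed: int = 0, epochs: int = 2000, lr: float = 0.02) -> FactorizationMachine:
    """Fit an FM by Adam on the L2-regularized squared loss (w0 unpenalized)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) == 0:
        raise ValueError("cannot fit FM on empty data")
    if not np.all(np.isfinite(y)):
        raise ValueError("acquisition targets must be finite")
    n, d = X.shape
    rng = np.random.default_rng(seed)
    w0 = np.array([y.mean()])
    w = np.zeros(d)
    V = rng.normal(0, 0.01, (d, rank))
    opt = _Adam([w0, w, V], lr)
    for _ in range(epochs):
        XV = X @ V
        pred = w0[0] + X @ w + 0.5 * ((XV ** 2).sum(1) - (X ** 2) @ (V ** 2).sum(1))
        err = (pred - y) / n
        gw0 = np.array([err.sum()])
        gw = X.T @ err + lam * w
        gV = X.T @ (err[:, None] * XV) - (((X ** 2).T @ err)[:, None]) * V + lam * V
        opt.step([gw0, gw, gV])
    return FactorizationMachine(w0=float(w0[0]), w=w, V=V)


# --------------------------------------------------------------------------
# QUBO compilation and simulated annealing
# --------------------------------------------------------------------------

@dataclass
class QUBO:
    """Upper-triangular quadratic form E(x) = x^T Q x + offset over binary x."""

    Q: np.ndarray
    offset: float = 0.0

    def energy(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        return float(x @ self.Q @ x + self.offset)

    def energies(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.einsum("ni,ij,nj->n", X, self.Q, X) + self.offset

    @property
    def d(self) -> int:
        return self.Q.shape[0]


def fm_to_qubo(fm: FactorizationMachine) -> QUBO:
    """Compile an FM into the QUBO whose minimum is the FM's maximum.

    The annealer minimizes energy, so the FM prediction is negated here,
    once: Q_ii = -w_i, Q_ij = -<v_i, v_j> (i < j), offset = -w0.
    """
    d = len(fm.w)
    gram = fm.V @ fm.V.T
    Q = np.triu(-gram, k=1)
    Q[np.diag_indices(d)] = -fm.w
    return QUBO(Q=Q, offset=-fm.w0)


@njit
def _sa_sweeps(h, S, x, u, betas):
    """In-place single-flip Metropolis sweeps; u is (sweeps, d) uniforms."""
    d = h.shape[0]
    n_sweeps = betas.shape[0]
    for s in range(n_sweeps):
        beta = betas[s]
        for i in range(d):
            field = h[i]
            for j in range(d):
                field += S[i, j] * x[j]
            delta = (1.0 - 2.0 * x[i]) * field
            if delta <= 0.0 or u[s, i] < np.exp(-beta * delta):
                x[i] = 1.0 - x[i]


def anneal_sample(qubo: QUBO, n_samples: int = 50, sweeps: int = 1000,
                  seed: int = 0) -> np.ndarray:
    """Sample low-energy binary vectors by restarted simulated annealing.

    Each of *n_samples* restarts anneals from a random state through a
    geometric temperature ladder; the final states are returned sorted by
    ascending energy (duplicates allowed).  Deterministic given *seed*.
    """
    d = qubo.d
    if d < 1:
        raise ValueError("QUBO must have at least one variable")
    h = np.ascontiguousarray(np.diag(qubo.Q).astype(float))
    S = qubo.Q + qubo.Q.T
    np.fill_diagonal(S, 0.0)
    S = np.ascontiguousarray(S, dtype=float)
    # temperature ladder spanning the largest possible single-flip move
    scale = float(np.max(np.abs(h) + np.sum(np.abs(S), axis=1)))
    t_hot = max(scale, 1e-9)
    t_cold = max(1e-3 * t_hot, 1e-9)
    betas = 1.0 / np.geomspace(t_hot, t_cold, max(sweeps, 1))
    rng = np.random.default_rng(seed)
    out = np.empty((n_samples, d))
    for k in range(n_samples):
        x = rng.integers(0, 2, size=d).astype(float)
        u = rng.random((max(sweeps, 1), d))
        _sa_sweeps(h, S, x, u, betas)
        out[k] = x
    order = np.argsort(qubo.energies(out), kind="stable")
    return out[order].astype(np.int8)


# --------------------------------------------------------------------------
# Acquisition and the optimizer loop
# --------------------------------------------------------------------------

def acquisition(vec, archive: ParetoArchive) -> float:
    """Hypervolume improvement of a candidate point over the current front.

    Zero for points dominated by (or duplicating) an archived point.
    """
    v = vec.as_array() if isinstance(vec, ObjectiveVector) else np.asarray(vec, float)
    for _, w in archive.entries:
        if dominates(w, v) or np.array_equal(w, v):
            return 0.0
    return archive.hypervolume_with(v) - archive.hypervolume()


def _rank_targets(vectors: np.ndarray) -> np.ndarray:
    """Dense non-domination scalarization: y = 1 / (1 + domination count).

    Every Pareto-front point scores 1 regardless of which objective it
    excels in, points deeper in the dominated region score progressively
    less — a dense regression signal that still rewards the whole
    spectrum of trade-offs.
    """
    V = np.asarray(vectors, dtype=float)
    counts = np.empty(len(V))
    for j in range(len(V)):
        counts[j] = np.sum(np.all(V >= V[j], axis=1) & np.any(V > V[j], axis=1))
    return 1.0 / (1.0 + counts)


def _exclusive_contribution(seq: str, v: np.ndarray, archive: ParetoArchive) -> float:
    """HVI of an already-archived point w.r.t. the front without it."""
    others = [w for s, w in archive.entries if s != seq]
    if not others:
        return archive.hypervolume()
    rest = ParetoArchive(reference_point=archive.reference_point,
                         objective_scale=archive.objective_scale)
    rest.entries = [(s, w) for s, w in archive.entries if s != seq]
    return rest.hypervolume_with(v) - rest.hypervolume()


@dataclass
class RunState:
    """State of one optimizer run: evaluations, archive, progress traces."""

    archive: ParetoArchive
    evaluated: dict[str, ObjectiveVector] = field(default_factory=dict)
    generated: list[tuple[str, ObjectiveVector]] = field(default_factory=list)
    budget: int = 0
    seed: int = 0
    n_initial: int = 0

    def best_generated(self) -> np.ndarray | None:
        """Componentwise best objective values over budget-consuming evaluations."""
        if not self.generated:
            return None
        return np.stack([v.as_array() for _, v in self.generated]).max(axis=0)

    def traces_frame(self):
        import pandas as pd

        hv = self.archive.hv_history
        best = self.archive.best_so_far
        return pd.DataFrame({
            "evaluation": [i for i, _ in hv],
            "hypervolume": [h for _, h in hv],
            "best_f_mean": [b[0] for b in best],
            "best_f_stab": [b[1] for b in best],
            "best_f_sol": [b[2] for b in best],
        })


def random_generate(n: int, length: int, alphabet: str = AA20,
                    seed: int = 0) -> list[str]:
    """n i.i.d. uniform-residue sequences of the given length."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(alphabet), size=(n, length))
    return ["".join(alphabet[i] for i in row) for row in idx]


def moqa_run(
    dataset: LabeledDataset,
    ensemble: PredictorEnsemble,
    scorer: SolubilityScorer,
    budget: int = 2000,
    seed: int = 0,
    *,
    autoencoder: BinaryAutoencoder | None = None,
    latent_dim: int = 64,
    batch_size: int = 20,
    fm_rank: int = 8,
    fm_lambda: float = 1e-3,
    fm_epochs: int = 400,
    fm_lr: float = 0.05,
    fm_target: str = "rank",
    sa_samples: int = 32,
    sa_sweeps: int = 200,
    n_random_init: int = 100,
    ae_config: AutoencoderConfig | None = None,
) -> RunState:
    """One optimizer run: propose by QUBO sampling, evaluate, refit, repeat.

    The FM is warm-started on the labeled training sequences' latent
    codes plus *n_random_init* random codes (these seed evaluations do
    not consume *budget*).  Each iteration fits the FM to a scalar
    acquisition target, compiles and anneals the QUBO, decodes a batch of
    distinct unseen sequences, evaluates them, and updates the archive.
    Deterministic given *seed*.

    ``fm_target`` selects the surrogate's regression target:

    ``rank`` (default)
        Dense non-domination scalarization (1 / (1 + domination count));
        every front point scores 1 whichever trade-off it realizes.
    ``hvi``
        Hypervolume improvement over the current front (exclusive
        contribution for archived front members).  Faithful to
        hypervolume but sparse — almost all dominated points give target
        zero, which starves the surrogate of gradient signal.
    """
    if fm_target not in {"rank", "hvi"}:
        raise ValueError(f"unknown fm_target {fm_target!r}")
    if budget < 0:
        raise ValueError("budget must be >= 0")
    if budget and budget < batch_size:
        raise ValueError(f"budget {budget} smaller than batch size {batch_size}")
    rng = np.random.default_rng(seed)
    train_seqs = list(dict.fromkeys(dataset.positives + dataset.negatives))
    if autoencoder is None:
        cfg = ae_config or AutoencoderConfig(seed=seed)
        autoencoder = train_autoencoder(train_seqs, latent_dim, cfg,
                                        alphabet=ensemble.alphabet)
    d = autoencoder.latent_dim

    # seed pool: training latents + random latents, deduplicated by sequence
    latents: list[np.ndarray] = []
    lat_seqs: list[str] = []
    evaluated: dict[str, ObjectiveVector] = {}
    for s in train_seqs:
        latents.append(autoencoder.encode(s).astype(float))
        lat_seqs.append(s)
    for _ in range(n_random_init):
        z = rng.integers(0, 2, size=d).astype(float)
        latents.append(z)
        lat_seqs.append(autoencoder.decode(z))
    for s in lat_seqs:
        if s not in evaluated:
            evaluated[s] = evaluate(s, ensemble, scorer)

    pool = np.stack([evaluated[s].as_array() for s in evaluated])
    reference = pool.min(axis=0) - 1e-6
    scale = pool.max(axis=0) - reference
    scale[scale <= 0] = 1.0
    archive = ParetoArchive(reference_point=reference, objective_scale=scale)
    eval_index = 0
    for s in evaluated:
        archive.update(s, evaluated[s], index=eval_index)
        eval_index += 1
    state = RunState(archive=archive, evaluated=evaluated, budget=budget,
                     seed=seed, n_initial=len(evaluated))

    used = 0
    iteration = 0
    while used < budget:
        if fm_target == "rank":
            V = np.stack([evaluated[s].as_array() for s in lat_seqs])
            y = _rank_targets(V)
        else:
            # exclusive HVI for front members, plain HVI (0) otherwise
            front_seqs = {s for s, _ in archive.entries}
            y = np.empty(len(latents))
            for i, s in enumerate(lat_seqs):
                v = evaluated[s].as_array()
                if s in front_seqs:
                    y[i] = _exclusive_contribution(s, v, archive)
                else:
                    y[i] = acquisition(v, archive)
        X = np.stack(latents)
        fm = fit_fm(X, y, rank=fm_rank, lam=fm_lambda,
                    seed=seed + 7919 * iteration, epochs=fm_epochs, lr=fm_lr)
        qubo = fm_to_qubo(fm)
        samples = anneal_sample(qubo, n_samples=sa_samples, sweeps=sa_sweeps,
                                seed=int(rng.integers(2 ** 31)))

        # The annealer often collapses onto one already-evaluated optimum,
        # so a single QUBO solve rarely yields a full batch of new
        # sequences.  Build a proposal pool from the distinct annealed
        # states plus seeded bit-flip perturbations of the lowest-energy
        # ones, screen the pool with the surrogate itself, and evaluate
        # the top-predicted unseen sequences (uniform random codes only
        # as a last resort).
        want = min(batch_size, budget - used)
        pool_codes = [z.astype(float) for z in samples]
        n_top = min(len(samples), 8)
        for _ in range(20 * want):
            z = samples[rng.integers(0, n_top)].astype(float).copy()
            flips = rng.choice(d, size=int(rng.integers(1, 6)), replace=False)
            z[flips] = 1.0 - z[flips]
            pool_codes.append(z)
        batch: list[tuple[np.ndarray, str]] = []
        seen_in_batch: set[str] = set()
        pool_arr = np.stack(pool_codes)
        for idx in np.argsort(qubo.energies(pool_arr), kind="stable"):
            z = pool_arr[idx]
            s = autoencoder.decode(z)
            if s in evaluated or s in seen_in_batch:
                continue
            batch.append((z, s))
            seen_in_batch.add(s)
            if len(batch) == want:
                break
        attempts = 0
        while len(batch) < want and attempts < 100 * want:
            attempts += 1
            z = rng.integers(0, 2, size=d).astype(float)
            s = autoencoder.decode(z)
            if s in evaluated or s in seen_in_batch:
                continue
            batch.append((z, s))
            seen_in_batch.add(s)
        if not batch:
            logger.warning("run %d: no new sequences reachable; stopping at %d/%d",
                           seed, used, budget)
            break
        for z, s in batch:
            v = evaluate(s, ensemble, scorer)
            evaluated[s] = v
            state.generated.append((s, v))
            latents.append(z)
            lat_seqs.append(s)
            archive.update(s, v, index=eval_index)
            eval_index += 1
            used += 1
        iteration += 1
    return state


def merge_runs(states: list[RunState], include_initial: bool = False):
    """Union of run outputs with exact string deduplication (first kept).

    Conflicting objective vectors for the same sequence across runs keep
    the first-seen values; the discrepancy is logged.
    """
    import pandas as pd

    if not states:
        raise ValueError("need at least one run")
    rows: dict[str, np.ndarray] = {}
    n_conflicts = 0
    for state in states:
        items = (
            list(state.evaluated.items()) if include_initial else state.generated
        )
        for s, v in items:
            arr = v.as_array()
            if s in rows:
                if not np.allclose(rows[s], arr):
                    n_conflicts += 1
            else:
                rows[s] = arr
    if n_conflicts:
        logger.warning("merge_runs: %d sequences had conflicting objective "
                       "vectors; kept first-seen values", n_conflicts)
    return pd.DataFrame(
        [{"sequence": s, "f_mean": v[0], "f_stab": v[1], "f_sol": v[2]}
         for s, v in rows.items()]
    )
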