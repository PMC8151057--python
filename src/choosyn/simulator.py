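"""Pseudo-real surface-EMG simulator for cyclic locomotion.

Generates ground-truth synergy sets (non-negative muscle weight vectors W
and cycle-locked activation coefficients C), combines them into augmented
"simulated subjects", and synthesizes raw-looking sEMG by modulating each
muscle's envelope ``W_muscle @ C`` with a zero-mean unit-variance Gaussian
carrier, optionally adding background Gaussian noise with standard
deviation ``10**(-SNR/20)`` to reach a prescribed signal-to-noise ratio.

Everything is generated directly on the normalized timebase of 1000
samples per gait cycle (nominally one cycle per second, i.e. 1000 Hz),
which is the timebase the downstream extraction pipeline operates on.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Iterator
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptyInputError,
    GenerationFailureError,
    IncompatibleSetsError,
    OrderExceedsMusclesError,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruthSet",
    "SimulatedRecording",
    "DatasetConfig",
    "SimulatedDataset",
    "generate_ground_truth",
    "augment_sets",
    "reconstruct_envelope",
    "synthesize_emg",
    "build_simulated_dataset",
    "DEFAULT_MUSCLE_NAMES",
]

CYCLE_LENGTH = 1000

#: Typical 12-channel lower-limb + trunk montage used in gait studies.
DEFAULT_MUSCLE_NAMES = (
    "GMD", "TFL", "RF", "VM", "LH", "MH",
    "LGS", "PL", "SOL", "TA", "LDR", "LDL",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable parameters of the ground-truth generator.

    Weight vectors are sparse-ish non-negative loadings: each synergy owns a
    disjoint subset of "primary" muscles with strong loadings, plus sparse
    weak cross-talk loadings elsewhere.  Activation coefficients are sums of
    1-2 Gaussian bursts per gait cycle with small cycle-to-cycle jitter,
    emulating the burst-like, cycle-locked activations seen in walking.
    """

    distinctness_cap: float = 0.6          # max pairwise weight-column cosine
    coeff_distinctness_cap: float = 0.6    # max pairwise activation cosine
    max_retries: int = 200
    primary_weight_range: tuple[float, float] = (0.6, 1.0)
    crosstalk_prob: float = 0.05
    crosstalk_range: tuple[float, float] = (0.05, 0.18)
    two_burst_prob: float = 0.0
    #: burst FWHM as a fraction of the synergy's phase slot (cycle / true_n),
    #: drawn once per set; within a set, synergies recruiting more muscles
    #: get proportionally narrower bursts so that every synergy contributes
    #: a comparable share of energy to the amplitude-normalized envelopes.
    burst_width_frac_of_slot: tuple[float, float] = (0.30, 0.45)
    burst_amp_range: tuple[float, float] = (0.5, 1.0)
    second_burst_scale: tuple[float, float] = (0.3, 0.7)
    tonic_level: tuple[float, float] = (0.04, 0.10)  # baseline / burst amp
    center_jitter_frac: float = 0.02       # cycle-to-cycle burst-center sd
    amp_jitter_sigma: float = 0.05         # lognormal sigma on burst amplitude


@dataclass
class GroundTruthSet:
    """A known synergy decomposition: ``envelopes = weights @ coefficients``.

    ``weights`` is (muscles, true_n) with unit-norm columns; ``coefficients``
    is (true_n, T) with T = cycle_length * n_cycles, scaled so the largest
    reconstructed envelope value equals 1 (arbitrary units).
    """

    weights: np.ndarray
    coefficients: np.ndarray
    true_n: int
    cycle_length: int = CYCLE_LENGTH
    n_cycles: int = 1
    seed: int | None = None

    @property
    def n_muscles(self) -> int:
        return self.weights.shape[0]

    def validate(self) -> None:
        m, n = self.weights.shape
        nc, t = self.coefficients.shape
        if n != self.true_n or nc != self.true_n:
            raise ValueError("factor shapes inconsistent with true_n")
        if t != self.cycle_length * self.n_cycles:
            raise ValueError("coefficient length is not a multiple of cycle_length")
        if (self.weights < 0).any() or (self.coefficients < 0).any():
            raise ValueError("factors must be non-negative")
        if not (self.weights.max(axis=0) > 0).all():
            raise ValueError("every weight column needs a positive entry")


@dataclass
class SimulatedRecording:
    """Synthetic raw sEMG: ``signal`` is (samples, muscles), a.u."""

    signal: np.ndarray
    snr_db: float | None                   # None = no additive noise
    events: np.ndarray                     # 0-based cycle starts
    truth: GroundTruthSet
    carrier_seed: int = 0
    noise_seed: int = 0
    set_id: str = ""

    def validate(self) -> None:
        ev = np.asarray(self.events)
        if ev[0] != 0 or (np.diff(ev) != self.truth.cycle_length).any():
            raise ValueError("events must start at 0 with cycle_length spacing")
        if len(ev) != self.truth.n_cycles:
            raise ValueError("one event per cycle expected")
        if np.isnan(self.signal).any():
            raise ValueError("signal contains NaNs")


def _draw_weights(true_n: int, m: int, rng: np.random.Generator,
                  cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sparse non-negative loadings; returns (W, primary-muscle counts)."""
    W = np.zeros((m, true_n))
    muscles = rng.permutation(m)
    chunks = np.array_split(muscles, true_n)
    lo, hi = cfg.primary_weight_range
    clo, chi = cfg.crosstalk_range
    for i, chunk in enumerate(chunks):
        W[chunk, i] = rng.uniform(lo, hi, size=len(chunk))
        others = np.setdiff1d(muscles, chunk)
        mask = rng.uniform(size=len(others)) < cfg.crosstalk_prob
        W[others[mask], i] = rng.uniform(clo, chi, size=int(mask.sum()))
    n_primary = np.array([len(c) for c in chunks])
    return W / np.linalg.norm(W, axis=0, keepdims=True), n_primary


def _max_pairwise_cosine(W: np.ndarray) -> float:
    G = (W / np.linalg.norm(W, axis=0, keepdims=True)).T @ (
        W / np.linalg.norm(W, axis=0, keepdims=True))
    iu = np.triu_indices_from(G, k=1)
    return float(G[iu].max()) if iu[0].size else 0.0


def _draw_coefficients(true_n: int, n_cycles: int, cycle_length: int,
                       n_primary: np.ndarray, rng: np.random.Generator,
                       cfg: GeneratorConfig) -> np.ndarray:
    """Cycle-locked Gaussian-burst activations, one phase slot per synergy.

    Gait synergies fire in an ordered sequence of gait-cycle phases
    (weight acceptance, push-off, swing, ...), so each synergy's primary
    burst center is drawn inside its own slot of the cycle; an optional
    weaker secondary burst may ride next to the primary one (a double-burst
    shape).  The gait cycle is treated as circular -- heel strike is an
    arbitrary phase origin -- so bursts wrap around the cycle boundary.
    A small tonic baseline (postural tone) rides under the bursts, and
    burst centers and amplitudes jitter slightly from cycle to cycle.
    """
    t = np.arange(cycle_length)
    C = np.zeros((true_n, n_cycles * cycle_length))
    phase0 = rng.uniform()                  # random origin of the slot ring
    slot_width = cycle_length / true_n
    slot_order = rng.permutation(true_n)
    set_width = rng.uniform(*cfg.burst_width_frac_of_slot)
    set_tonic = rng.uniform(*cfg.tonic_level)
    mean_primary = n_primary.mean()
    for i in range(true_n):
        s = slot_order[i]
        n_bursts = 2 if rng.uniform() < cfg.two_burst_prob else 1
        centers = np.empty(n_bursts)
        centers[0] = ((phase0 + (s + rng.uniform(0.35, 0.65)) / true_n) % 1.0
                      ) * cycle_length
        amps = np.empty(n_bursts)
        amps[0] = rng.uniform(*cfg.burst_amp_range)
        budget = (set_width * rng.uniform(0.95, 1.05) * slot_width
                  * mean_primary / n_primary[i])
        if n_bursts == 1:
            fwhm = np.array([budget])
        else:
            amps[1] = amps[0] * rng.uniform(*cfg.second_burst_scale)
            # both bursts sized so peak-normalized energy matches the budget
            a2 = (amps[1] / amps[0]) ** 2
            fwhm = np.full(2, budget / (1.0 + a2))
            # bimodal burst: the second mode stays inside the same slot
            centers[1] = centers[0] + rng.choice((-1.0, 1.0)) * rng.uniform(
                0.6, 0.8) * fwhm[0]
        sigmas = fwhm / 2.3548200450309493  # FWHM -> Gaussian sigma
        tonic = amps[0] * set_tonic
        for c in range(n_cycles):
            row = np.full(cycle_length, tonic)
            for b in range(n_bursts):
                mu = centers[b] + rng.normal(0.0, cfg.center_jitter_frac * cycle_length)
                amp = amps[b] * rng.lognormal(0.0, cfg.amp_jitter_sigma)
                # circular burst: evaluate at the center and its two wraps
                for shift in (-cycle_length, 0.0, cycle_length):
                    row += amp * np.exp(
                        -0.5 * ((t - mu + shift) / sigmas[b]) ** 2)
            C[i, c * cycle_length:(c + 1) * cycle_length] = row
    return C


def generate_ground_truth(true_n: int, m: int = 12, n_cycles: int = 150,
                          seed: int = 0,
                          config: GeneratorConfig | None = None) -> GroundTruthSet:
    """Draw a random ground-truth synergy set.

    Weight columns are resampled (up to ``config.max_retries`` times) until
    all pairwise cosines are below the distinctness cap, so the synthesized
    synergies are well separated by construction.  The coefficient matrix is
    rescaled so the largest reconstructed envelope sample equals 1 a.u.,
    which anchors the additive-noise SNR definition downstream.
    """
    cfg = config or GeneratorConfig()
    if true_n > m:
        raise OrderExceedsMusclesError(
            f"true_n={true_n} exceeds number of muscles m={m}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    W = n_primary = None
    for _ in range(cfg.max_retries):
        cand, n_prim = _draw_weights(true_n, m, rng, cfg)
        if true_n < 2 or _max_pairwise_cosine(cand) <= cfg.distinctness_cap:
            W, n_primary = cand, n_prim
            break
    if W is None:
        raise GenerationFailureError(
            f"could not satisfy distinctness cap {cfg.distinctness_cap} "
            f"after {cfg.max_retries} tries (true_n={true_n}, m={m})")
    C = None
    for _ in range(cfg.max_retries):
        cand = _draw_coefficients(true_n, n_cycles, CYCLE_LENGTH, n_primary,
                                  rng, cfg)
        # distinctness judged on the one-cycle burst template (cycle-average,
        # per-row tonic baseline removed: shared postural tone is benign)
        template = cand.reshape(true_n, n_cycles, CYCLE_LENGTH).mean(axis=1)
        template = template - template.min(axis=1, keepdims=True)
        if true_n < 2 or _max_pairwise_cosine(template.T) <= cfg.coeff_distinctness_cap:
            C = cand
            break
    if C is None:
        raise GenerationFailureError(
            f"could not satisfy activation distinctness cap "
            f"{cfg.coeff_distinctness_cap} after {cfg.max_retries} tries")
    C /= (W @ C).max()
    gt = GroundTruthSet(weights=W, coefficients=C, true_n=true_n,
                        cycle_length=CYCLE_LENGTH, n_cycles=n_cycles, seed=seed)
    gt.validate()
    return gt


def augment_sets(subjects: list[GroundTruthSet]) -> list[GroundTruthSet]:
    """All weight/coefficient cross-combinations of a group of subjects.

    ``k`` subjects yield ``k**2`` sets, ordered with the weight donor as the
    outer index: (W1,C1), (W1,C2), ..., (Wk,Ck).  Each combined coefficient
    matrix is rescaled so the combined envelope peaks at 1 a.u.
    """
    if not subjects:
        raise EmptyInputError("no ground-truth sets to augment")
    n0, m0 = subjects[0].true_n, subjects[0].n_muscles
    for s in subjects:
        if s.true_n != n0 or s.n_muscles != m0:
            raise IncompatibleSetsError(
                "all subjects must share true_n and muscle count")
    out = []
    for wi, cj in itertools.product(subjects, subjects):
        C = cj.coefficients.copy()
        C /= (wi.weights @ C).max()
        out.append(GroundTruthSet(
            weights=wi.weights.copy(), coefficients=C, true_n=n0,
            cycle_length=cj.cycle_length, n_cycles=cj.n_cycles, seed=None))
    return out


def reconstruct_envelope(truth: GroundTruthSet, muscle: int) -> np.ndarray:
    """Noiseless envelope of one muscle: its weight row times C."""
    if not 0 <= muscle < truth.n_muscles:
        raise IndexError(f"muscle index {muscle} out of range")
    return truth.weights[muscle] @ truth.coefficients


def synthesize_emg(truth: GroundTruthSet, snr_db: float | None,
                   carrier_seed: int = 0, noise_seed: int = 1,
                   set_id: str = "") -> SimulatedRecording:
    """Raw-looking sEMG from a ground truth set.

    Per muscle: ``S = envelope * G_S + G_N`` with ``G_S`` an i.i.d. standard
    normal carrier (independent across muscles and samples) and, unless
    ``snr_db`` is None, ``G_N`` i.i.d. normal background noise with sigma
    ``10**(-snr_db/20)``.
    """
    if snr_db is not None and not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite; use None for no additive noise")
    E = truth.weights @ truth.coefficients          # (m, T)
    t_len = E.shape[1]
    carrier = np.random.default_rng(carrier_seed).standard_normal(E.shape)
    signal = (E * carrier).T                        # (T, m)
    if snr_db is not None:
        sigma = 10.0 ** (-snr_db / 20.0)
        noise = np.random.default_rng(noise_seed).standard_normal((t_len, E.shape[0]))
        signal = signal + sigma * noise
    events = np.arange(truth.n_cycles) * truth.cycle_length
    rec = SimulatedRecording(signal=signal, snr_db=snr_db, events=events,
                             truth=truth, carrier_seed=carrier_seed,
                             noise_seed=noise_seed, set_id=set_id)
    rec.validate()
    return rec


@dataclass(frozen=True)
class DatasetConfig:
    """Grid defining a full simulated benchmark dataset.

    Defaults mirror a 5-minute-walk study design: three true synergy
    numbers with five subjects each, augmented to 25 sets per level, under
    a no-additive-noise condition plus four SNR levels, for 375 recordings.
    """

    true_n_levels: tuple[int, ...] = (4, 5, 6)
    subjects_per_level: int = 5
    snr_conditions: tuple[float | None, ...] = (None, 30.0, 25.0, 20.0, 15.0)
    n_cycles: int = 150
    n_muscles: int = 12
    master_seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)


class SimulatedDataset:
    """Lazy, manifest-driven collection of simulated recordings.

    Recordings are synthesized on demand during iteration so the full grid
    never has to sit in memory; the manifest records every seed, which makes
    the dataset a pure function of (config, master seed).
    """

    def __init__(self, config: DatasetConfig):
        self.config = config
        if not config.snr_conditions:
            raise EmptyInputError("snr_conditions must be non-empty")
        rng = np.random.default_rng(config.master_seed)
        self._levels = []
        records = []
        for level, true_n in enumerate(config.true_n_levels):
            subject_seeds = [int(s) for s in
                             rng.integers(0, 2 ** 31, size=config.subjects_per_level)]
            self._levels.append({"true_n": true_n, "subject_seeds": subject_seeds})
            k = config.subjects_per_level
            for i, j in itertools.product(range(k), range(k)):
                for cond in config.snr_conditions:
                    records.append({
                        "set_id": f"n{true_n}_W{i + 1}C{j + 1}_"
                                  f"{'nonoise' if cond is None else f'snr{cond:g}'}",
                        "level": level,
                        "true_n": true_n,
                        "w_subject": i,
                        "c_subject": j,
                        "snr_db": cond,
                        "carrier_seed": int(rng.integers(0, 2 ** 31)),
                        "noise_seed": int(rng.integers(0, 2 ** 31)),
                    })
        self.manifest = {
            "config": _config_dict(config),
            "levels": self._levels,
            "records": records,
        }
        self._cache_level: int | None = None
        self._cache_sets: list[GroundTruthSet] | None = None

    def __len__(self) -> int:
        return len(self.manifest["records"])

    def _augmented_level(self, level: int) -> list[GroundTruthSet]:
        if self._cache_level != level:
            info = self._levels[level]
            cfg = self.config
            subjects = [generate_ground_truth(info["true_n"], cfg.n_muscles,
                                              cfg.n_cycles, seed=s,
                                              config=cfg.generator)
                        for s in info["subject_seeds"]]
            self._cache_sets = augment_sets(subjects)
            self._cache_level = level
        return self._cache_sets

    def __iter__(self) -> Iterator[SimulatedRecording]:
        k = self.config.subjects_per_level
        for rec in self.manifest["records"]:
            sets = self._augmented_level(rec["level"])
            truth = sets[rec["w_subject"] * k + rec["c_subject"]]
            yield synthesize_emg(truth, rec["snr_db"],
                                 carrier_seed=rec["carrier_seed"],
                                 noise_seed=rec["noise_seed"],
                                 set_id=rec["set_id"])


def _config_dict(config: DatasetConfig) -> dict:
    d = dataclasses.asdict(config)
    d["generator"] = dataclasses.asdict(config.generator)
    return d


def build_simulated_dataset(config: DatasetConfig | None = None) -> SimulatedDataset:
    """Build the lazily-evaluated simulated dataset for a config grid."""
    return SimulatedDataset(config or DatasetConfig())
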