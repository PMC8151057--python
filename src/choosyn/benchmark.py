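"""End-to-end benchmark harness over simulated datasets.

Runs each simulated recording through preprocessing, the full NMF order
sweep, cross-subgroup sorting, and every selection criterion, then scores
methods per noise condition with the fraction of correct classifications,
mean error (ME) and root-mean-square error (RMSE), in numbers of
synergies:

    ME   = mean(n_i - n_true,i)
    RMSE = sqrt(mean((n_i - n_true,i)**2))

Criteria that decline to select (threshold never crossed, no plateau) are
counted as incorrect classifications but excluded from ME/RMSE, with the
failure count reported separately.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ChoosynError, NoSelectionError, UndefinedMetricError
from .extraction import NmfParams, build_synergy_stack, extract_all
from .preprocessing import EmgRecording, preprocess
from .selection_choosyn import build_profile, select_n
from .selection_vaf import build_vaf_curve, evaf, pvaf, tvaf
from .simulator import SimulatedDataset

__all__ = [
    "PipelineConfig",
    "desk_preset",
    "full_preset",
    "WalkAnalysis",
    "TrialOutcome",
    "MethodScore",
    "BenchmarkReport",
    "ALL_METHODS",
    "mean_error",
    "rmse",
    "analyze_recording",
    "run_benchmark",
]

ALL_METHODS = ("tvaf90", "tvaf95", "evaf", "pvaf", "choosyn")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the extraction + selection pipeline needs to run."""

    fs_nominal: float = 1000.0
    n_range: tuple[int, int] = (1, 8)
    nmf: NmfParams = field(default_factory=NmfParams)
    kmeans_replicas: int = 15
    tvaf_thresholds: tuple[float, float] = (90.0, 95.0)
    pvaf_mse_threshold: float = 1e-2
    scaled_down: bool = False


def full_preset() -> PipelineConfig:
    """Full-size analysis: 5 NMF restarts, full iteration budget."""
    return PipelineConfig()


def desk_preset() -> PipelineConfig:
    """Reduced-cost preset for single-CPU benchmark sweeps.

    Keeps the algorithms and tolerances intact but runs 3 NMF restarts,
    caps alternating iterations at 150 and fits the factors on every 5th
    envelope sample (the envelopes are 12 Hz low-passed, so one-fifth
    resolution still oversamples them; full-resolution coefficients are
    recovered by one exact NNLS solve).  Reports produced under this
    preset are flagged as scaled down.
    """
    return PipelineConfig(
        nmf=NmfParams(max_iter=150, reruns=3, decimate=5),
        scaled_down=True,
    )


@dataclass
class WalkAnalysis:
    """All per-walk artifacts: stack, VAF curve, profile, selections."""

    stack: object
    vaf_curve: object
    profile: object
    selections: dict[str, int | None]
    diagnostics: dict


def _select_all(curve, profile, config: PipelineConfig,
                methods: tuple[str, ...]) -> tuple[dict, dict]:
    selections: dict[str, int | None] = {}
    diagnostics: dict = {}
    t90, t95 = config.tvaf_thresholds
    runners: dict[str, Callable[[], int]] = {
        "tvaf90": lambda: tvaf(curve, t90),
        "tvaf95": lambda: tvaf(curve, t95),
        "evaf": lambda: evaf(curve),
        "pvaf": lambda: pvaf(curve, config.pvaf_mse_threshold),
    }
    for name in methods:
        if name == "choosyn":
            chosen, diag = select_n(profile)
            selections[name] = chosen
            diagnostics[name] = diag
            continue
        try:
            selections[name] = runners[name]()
        except (NoSelectionError, ChoosynError) as exc:
            selections[name] = None
            diagnostics[name] = {"failure": str(exc)}
    return selections, diagnostics


def analyze_recording(rec: EmgRecording, config: PipelineConfig | None = None,
                      seed: int = 0,
                      methods: tuple[str, ...] = ALL_METHODS) -> WalkAnalysis:
    """Preprocess one walk and run every requested selection criterion."""
    config = config or PipelineConfig()
    subs = preprocess(rec, fs_nominal=config.fs_nominal)
    results = extract_all(subs, n_range=config.n_range, seed=seed,
                          params=config.nmf)
    stack = build_synergy_stack(results, seed=seed,
                                replicas=config.kmeans_replicas)
    curve = build_vaf_curve(stack.vaf_per_subgroup)
    profile = build_profile(stack) if "choosyn" in methods else None
    selections, diagnostics = _select_all(curve, profile, config, methods)
    return WalkAnalysis(stack=stack, vaf_curve=curve, profile=profile,
                        selections=selections, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mean_error(selected: list[int], truth: list[int]) -> float:
    """Mean signed deviation of the selected order from the true one."""
    if len(selected) != len(truth):
        raise ValueError("length mismatch")
    if not selected:
        raise UndefinedMetricError("no valid trials for ME")
    return float(np.mean(np.asarray(selected) - np.asarray(truth)))


def rmse(selected: list[int], truth: list[int]) -> float:
    """Root-mean-square deviation of the selected order from the true one."""
    if len(selected) != len(truth):
        raise ValueError("length mismatch")
    if not selected:
        raise UndefinedMetricError("no valid trials for RMSE")
    d = np.asarray(selected) - np.asarray(truth)
    return float(np.sqrt(np.mean(d.astype(float) ** 2)))


@dataclass
class TrialOutcome:
    set_id: str
    condition: str
    true_n: int
    selections: dict[str, int | None]


@dataclass
class MethodScore:
    n_total: int
    n_correct: int
    n_failed: int
    me: float | None
    rmse: float | None

    @property
    def fraction_correct(self) -> float:
        return self.n_correct / self.n_total


@dataclass
class BenchmarkReport:
    """Per-method, per-condition score table plus full per-trial log."""

    scores: dict[str, dict[str, MethodScore]]   # condition -> method -> score
    trials: list[TrialOutcome]
    manifest: dict
    methods: tuple[str, ...]
    seed: int
    scaled_down: bool

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "methods": list(self.methods),
            "scaled_down": self.scaled_down,
            "scores": {
                cond: {meth: dataclasses.asdict(s) | {
                    "fraction_correct": s.fraction_correct}
                    for meth, s in by_method.items()}
                for cond, by_method in self.scores.items()
            },
            "manifest": self.manifest,
        }
        return json.dumps(payload, indent=2)

    def trials_csv(self) -> str:
        header = ["set_id", "condition", "true_n", *self.methods]
        lines = [",".join(header)]
        for t in self.trials:
            row = [t.set_id, t.condition, str(t.true_n)]
            row += ["" if t.selections.get(m) is None else str(t.selections[m])
                    for m in self.methods]
            lines.append(",".join(row))
        return "\n".join(lines) + "\n"

    def to_text_table(self) -> str:
        conds = list(self.scores)
        out = []
        for block, fmt in (("fraction correct", None), ("ME", "me"),
                           ("RMSE", "rmse")):
            out.append(block)
            out.append("\t".join(["condition", *self.methods]))
            for cond in conds:
                row = [cond]
                for m in self.methods:
                    s = self.scores[cond][m]
                    if fmt is None:
                        row.append(f"{s.n_correct}/{s.n_total}")
                    else:
                        v = getattr(s, fmt)
                        row.append("n/a" if v is None else f"{v:.2f}")
                out.append("\t".join(row))
            out.append("")
        return "\n".join(out)


def _condition_label(snr_db: float | None) -> str:
    return "no noise" if snr_db is None else f"SNR = {snr_db:g} dB"


def score_trials(trials: list[TrialOutcome],
                 methods: tuple[str, ...]) -> dict[str, dict[str, MethodScore]]:
    """Aggregate per-trial selections into per-condition method scores."""
    by_cond: dict[str, list[TrialOutcome]] = {}
    for t in trials:
        by_cond.setdefault(t.condition, []).append(t)
    scores: dict[str, dict[str, MethodScore]] = {}
    for cond, ts in by_cond.items():
        scores[cond] = {}
        for m in methods:
            sel = [t.selections.get(m) for t in ts]
            valid = [(s, t.true_n) for s, t in zip(sel, ts) if s is not None]
            n_failed = sum(1 for s in sel if s is None)
            n_correct = sum(1 for s, nt in valid if s == nt)
            if valid:
                vs, vt = zip(*valid)
                scores[cond][m] = MethodScore(
                    n_total=len(ts), n_correct=n_correct, n_failed=n_failed,
                    me=mean_error(list(vs), list(vt)),
                    rmse=rmse(list(vs), list(vt)))
            else:
                scores[cond][m] = MethodScore(n_total=len(ts),
                                              n_correct=0, n_failed=n_failed,
                                              me=None, rmse=None)
    return scores


def run_benchmark(dataset: SimulatedDataset,
                  methods: tuple[str, ...] = ALL_METHODS,
                  config: PipelineConfig | None = None,
                  seed: int = 0,
                  progress: Callable[[str], None] | None = None
                  ) -> BenchmarkReport:
    """Score every selection criterion over a simulated dataset.

    Each recording's extraction seed is derived deterministically from the
    benchmark seed and the set id, so the report is a pure function of
    (dataset manifest, methods, config, seed).
    """
    config = config or PipelineConfig()
    trials = []
    for rec in dataset:
        rec_seed = int(np.random.SeedSequence(
            (seed, zlib.crc32(rec.set_id.encode()))).generate_state(1)[0]
            % (2 ** 31))
        emg = EmgRecording.from_simulated(rec)
        analysis = analyze_recording(emg, config=config, seed=rec_seed,
                                     methods=methods)
        trials.append(TrialOutcome(set_id=rec.set_id,
                                   condition=_condition_label(rec.snr_db),
                                   true_n=rec.truth.true_n,
                                   selections=analysis.selections))
        if progress is not None:
            progress(rec.set_id)
    scores = score_trials(trials, methods)
    return BenchmarkReport(scores=scores, trials=trials,
                           manifest=dataset.manifest, methods=methods,
                           seed=seed, scaled_down=config.scaled_down)
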