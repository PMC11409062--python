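"""Identification-accuracy benchmarking: condition runs, sweeps, bootstrap CIs.

A *condition* is one operating point of the simulated sequencer: signal
quality (p_max), detection set, fragment plan (or full-length input) and
indel error rates. Running a condition simulates readouts for every protein
in the database, identifies each readout, and reports the accuracy — the
fraction of proteins whose top hit is their true source — with a percentile
bootstrap 95% confidence interval. With multi-fragment plans both the
per-fragment accuracy (mean over the fragment repetitions) and the
combined accuracy (scores summed over fragments before the argmax) are
computed in a single pass.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .database import SequenceDatabase, read_fasta
from .hmm import ProfileParams, build_profile
from .search import IdentificationResult, combine_fragments, infer, score_database
from .simulate import (
    DeviceConfig,
    ErrorModel,
    FragmentPlan,
    protein_rng,
    sample_fragments,
    simulate_readout,
)

FULL_LENGTH = "full"


@dataclass(frozen=True)
class EvalResult:
    """Accuracy of one experimental condition.

    ``n_correct`` is the sum over proteins of the per-protein fraction of
    correct identifications (an integer for single-readout conditions, and
    possibly fractional when averaging over fragment repetitions), so
    ``accuracy = n_correct / n_proteins`` always holds.
    """

    condition: dict
    n_proteins: int
    n_correct: float
    accuracy: float
    ci_low: float
    ci_high: float
    tie_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must be in [0, 1]")
        if abs(self.accuracy - self.n_correct / self.n_proteins) > 1e-9:
            raise ValueError("accuracy must equal n_correct / n_proteins")
        if not self.ci_low - 1e-12 <= self.accuracy <= self.ci_high + 1e-12:
            raise ValueError("accuracy must lie inside its confidence interval")


@dataclass
class ConditionResult:
    """Per-fragment and (when applicable) combined results of one condition."""

    per_fragment: EvalResult
    combined: EvalResult | None = None


@dataclass
class SweepSpec:
    """Cartesian grid of experimental conditions.

    ``fragment_lengths`` may mix integers and the string ``"full"``;
    ``detection_sets`` are strings of one-letter codes (``"all"`` for the
    full alphabet).
    """

    p_max_grid: Sequence[float]
    fragment_lengths: Sequence = (FULL_LENGTH,)
    n_fragments: int = 1
    detection_sets: Sequence[str] = ("all",)
    insertion_rates: Sequence[float] = (0.0,)
    deletion_rates: Sequence[float] = (0.0,)
    seed: int = 0
    db_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("p_max_grid", "fragment_lengths", "detection_sets",
                     "insertion_rates", "deletion_rates"):
            if not list(getattr(self, name)):
                raise ValueError(f"{name} must be non-empty")

    def conditions(self) -> list[dict]:
        grid = itertools.product(
            self.p_max_grid,
            self.fragment_lengths,
            self.detection_sets,
            self.insertion_rates,
            self.deletion_rates,
        )
        return [
            {
                "p_max": p,
                "fragment_length": fl,
                "n_fragments": 1 if fl == FULL_LENGTH else self.n_fragments,
                "detection_set": det,
                "insertion_rate": ins,
                "deletion_rate": dele,
                "seed": self.seed,
            }
            for p, fl, det, ins, dele in grid
        ]


def compute_accuracy(results: Sequence[IdentificationResult]) -> EvalResult:
    """Fraction of correctly identified readouts (no confidence interval)."""
    if not results:
        raise ValueError("no identification results")
    flags = [bool(r.correct) for r in results]
    n = len(flags)
    n_correct = sum(flags)
    acc = n_correct / n
    return EvalResult(
        condition={},
        n_proteins=n,
        n_correct=n_correct,
        accuracy=acc,
        ci_low=acc,
        ci_high=acc,
        tie_fraction=sum(r.tie_flag for r in results) / n,
    )


def bootstrap_ci(
    correct_flags: Sequence[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of per-protein outcomes."""
    flags = np.asarray(correct_flags, dtype=float)
    if flags.size == 0:
        raise ValueError("no outcomes to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, flags.size, size=(n_boot, flags.size))
    means = flags[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _condition_seed(seed: int, condition: dict) -> int:
    key = "|".join(
        f"{k}={condition[k]}"
        for k in ("p_max", "fragment_length", "detection_set",
                  "insertion_rate", "deletion_rate")
        if k in condition
    )
    return int(np.random.SeedSequence([seed, zlib.crc32(key.encode())]).generate_state(1)[0])


def evaluate_condition(
    db: SequenceDatabase,
    device: DeviceConfig,
    fragment_plan: FragmentPlan | None = None,
    error_model: ErrorModel | None = None,
    seed: int = 0,
    params: ProfileParams | None = None,
    n_boot: int = 1000,
    condition: dict | None = None,
) -> ConditionResult:
    """Simulate, search and evaluate one condition over the whole database.

    Per-protein RNG substreams are derived from ``(seed, accession)``, so
    results do not depend on iteration order. Returns the per-fragment
    result and, for multi-fragment plans, the combined (summed-score)
    result from the same simulated readouts.
    """
    if condition is None:
        condition = {
            "p_max": device.p_max,
            "fragment_length": fragment_plan.length if fragment_plan else FULL_LENGTH,
            "n_fragments": fragment_plan.n_fragments if fragment_plan else 1,
            "detection_set": "".join(sorted(device.detection_set)),
            "insertion_rate": error_model.insertion_rate if error_model else 0.0,
            "deletion_rate": error_model.deletion_rate if error_model else 0.0,
            "seed": seed,
        }
    cond_seed = _condition_seed(seed, condition)
    multi = fragment_plan is not None and fragment_plan.n_fragments > 1

    per_protein_frac: list[float] = []
    combined_flags: list[float] = []
    n_ties = 0
    n_readouts = 0
    for record in db.records:
        rng = protein_rng(cond_seed, record.accession)
        if fragment_plan is not None:
            windows = sample_fragments(record, fragment_plan, rng=rng)
        else:
            windows = [(0, len(record))]
        frag_scores = []
        frag_correct = []
        for start, end in windows:
            readout = simulate_readout(
                record.sequence[start:end],
                device,
                error_model,
                accession=record.accession,
                fragment=(start, end),
                rng=rng,
            )
            profile = build_profile(readout, params)
            hits = score_database(profile, db)
            result = infer(hits, truth=record.accession, readout_id=readout.readout_id)
            frag_correct.append(bool(result.correct))
            n_ties += result.tie_flag
            n_readouts += 1
            if multi:
                frag_scores.append((readout.readout_id, hits))
        per_protein_frac.append(sum(frag_correct) / len(frag_correct))
        if multi:
            combined = infer(
                combine_fragments(frag_scores),
                truth=record.accession,
                readout_id=record.accession,
            )
            combined_flags.append(float(combined.correct))

    boot_rng = np.random.default_rng(np.random.SeedSequence([cond_seed, 0xB007]))
    lo, hi = bootstrap_ci(per_protein_frac, n_boot=n_boot, seed=boot_rng)
    n = len(per_protein_frac)
    per_fragment = EvalResult(
        condition=dict(condition, combined=False),
        n_proteins=n,
        n_correct=float(sum(per_protein_frac)),
        accuracy=float(np.mean(per_protein_frac)),
        ci_low=min(lo, float(np.mean(per_protein_frac))),
        ci_high=max(hi, float(np.mean(per_protein_frac))),
        tie_fraction=n_ties / n_readouts,
    )
    combined_res = None
    if multi:
        lo, hi = bootstrap_ci(combined_flags, n_boot=n_boot, seed=boot_rng)
        acc = float(np.mean(combined_flags))
        combined_res = EvalResult(
            condition=dict(condition, combined=True),
            n_proteins=n,
            n_correct=float(sum(combined_flags)),
            accuracy=acc,
            ci_low=min(lo, acc),
            ci_high=max(hi, acc),
            tie_fraction=n_ties / n_readouts,
        )
    return ConditionResult(per_fragment=per_fragment, combined=combined_res)


def run_condition(
    db: SequenceDatabase,
    device: DeviceConfig,
    fragment_plan: FragmentPlan | None = None,
    error_model: ErrorModel | None = None,
    combine: bool = False,
    seed: int = 0,
    params: ProfileParams | None = None,
    n_boot: int = 1000,
) -> EvalResult:
    """Evaluate one condition; ``combine=True`` returns the summed-fragment
    result instead of the per-fragment average."""
    res = evaluate_condition(
        db, device, fragment_plan, error_model, seed=seed, params=params, n_boot=n_boot
    )
    if combine:
        if res.combined is None:
            raise ValueError("combine=True requires a multi-fragment plan")
        return res.combined
    return res.per_fragment


def _detection_set(label: str):
    from .simulate import FULL_DETECTION_SET

    return FULL_DETECTION_SET if label in ("all", "") else frozenset(label)


_RESULT_COLUMNS = [
    "p_max", "fragment_length", "n_fragments", "detection_set",
    "insertion_rate", "deletion_rate", "combined",
    "n", "n_correct", "accuracy", "ci_low", "ci_high", "tie_fraction", "seed",
]


def _rows_of(res: ConditionResult) -> list[dict]:
    rows = []
    for ev in (res.per_fragment, res.combined):
        if ev is None:
            continue
        c = ev.condition
        rows.append(
            {
                "p_max": c["p_max"],
                "fragment_length": c["fragment_length"],
                "n_fragments": c["n_fragments"],
                "detection_set": c["detection_set"],
                "insertion_rate": c["insertion_rate"],
                "deletion_rate": c["deletion_rate"],
                "combined": bool(c["combined"]),
                "n": ev.n_proteins,
                "n_correct": ev.n_correct,
                "accuracy": ev.accuracy,
                "ci_low": ev.ci_low,
                "ci_high": ev.ci_high,
                "tie_fraction": ev.tie_fraction,
                "seed": c["seed"],
            }
        )
    return rows


_KEY_COLUMNS = ["p_max", "fragment_length", "n_fragments", "detection_set",
                "insertion_rate", "deletion_rate"]


def run_sweep(
    spec: SweepSpec,
    db: SequenceDatabase | None = None,
    out_path: str | Path | None = None,
    params: ProfileParams | None = None,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Run every condition of the grid; one row per (condition, reporting).

    If ``out_path`` is given, completed grid points found there are skipped
    on rerun and partial results are persisted after every condition.
    """
    if db is None:
        if spec.db_path is None:
            raise ValueError("either db or spec.db_path is required")
        db = read_fasta(spec.db_path)

    done = pd.DataFrame(columns=_RESULT_COLUMNS)
    if out_path is not None and Path(out_path).exists():
        done = pd.read_csv(out_path, sep="\t")
    done_keys = {
        tuple(str(row[k]) for k in _KEY_COLUMNS) for _, row in done.iterrows()
    }

    rows = [row for _, row in done.iterrows()]
    for cond in spec.conditions():
        key = tuple(str(cond[k]) for k in _KEY_COLUMNS)
        if key in done_keys:
            continue
        device = DeviceConfig(cond["p_max"], _detection_set(cond["detection_set"]))
        plan = (
            None
            if cond["fragment_length"] == FULL_LENGTH
            else FragmentPlan(int(cond["fragment_length"]), spec.n_fragments)
        )
        errors = (
            None
            if cond["insertion_rate"] == 0 and cond["deletion_rate"] == 0
            else ErrorModel(cond["insertion_rate"], cond["deletion_rate"])
        )
        res = evaluate_condition(
            db, device, plan, errors, seed=spec.seed, params=params,
            n_boot=n_boot, condition=cond,
        )
        rows.extend(_rows_of(res))
        if out_path is not None:
            pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(
                out_path, sep="\t", index=False
            )
    table = pd.DataFrame(rows, columns=_RESULT_COLUMNS).reset_index(drop=True)
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table
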