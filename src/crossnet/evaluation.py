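"""Simulation harness: type-I calibration, power and recovery.

These runs are the package's statistical acceptance surface. A calibration
run repeats the full pipeline on null synthetic instances (no planted
signal) and checks that the rejection rate at level alpha stays nominal;
a recovery run plants a known excess of cross-set edges and measures how
well ``observed - expected_null`` recovers it, plus power along a grid of
planted strengths.

Replicate seeds are ``master_seed + replicate_index``; everything is
reproducible from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field, asdict

import numpy as np

from .connectivity import NullConfig, connectivity_test
from .errors import ParameterError
from .synthetic import (
    SyntheticSpec,
    generate_interactome,
    make_seed_sets,
    plant_crosstalk,
)


@dataclass
class CalibrationSummary:
    """Null behaviour of the test across replicates."""

    n_reps: int
    alpha: float
    rejection_rate: float
    mean_z: float
    sd_z: float
    records: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RecoverySummary:
    """Planted-effect recovery along a grid of planted strengths."""

    q_grid: list[int]
    mean_excess: list[float]
    mean_q_added: list[float]
    relative_bias: list[float | None]
    power: list[float]
    alpha: float
    n_reps: int
    records: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _one_replicate(
    spec: SyntheticSpec,
    config: NullConfig,
    depth: int,
    rep_seed: int,
) -> tuple[dict, int]:
    s = replace(spec, seed=rep_seed)
    background = generate_interactome(s)
    set_a, set_b, _ = make_seed_sets(background, s)
    graph, truth = plant_crosstalk(
        background, set_a, set_b, s.planted_q, s.seed + 2
    )
    result = connectivity_test(
        graph, set_a, set_b, depth=depth, config=replace(config, seed=rep_seed)
    )
    record = {
        "seed": rep_seed,
        "z": result.z if result.z_defined else None,
        "p": result.p_empirical,
        "observed": result.observed,
        "expected_null": result.expected_null,
        "q_added": truth.q_added,
    }
    return record, truth.q_added


def calibration_run(
    spec: SyntheticSpec,
    config: NullConfig,
    n_reps: int,
    alpha: float,
    master_seed: int,
    depth: int = 1,
    keep_records: bool = True,
) -> CalibrationSummary:
    """Type-I error of the test under the null generator (no planted edges).

    Each replicate generates a fresh background graph and seed pair from
    ``spec`` (with ``seed = master_seed + i``), runs the full test, and the
    summary reports the fraction of empirical p-values <= alpha. With the
    add-one estimator, ``p <= alpha`` has probability exactly alpha under
    exchangeability whenever ``alpha * (n_perm + 1)`` is an integer and
    ties are absent.
    """
    if spec.planted_q != 0:
        raise ParameterError("calibration requires planted_q = 0")
    if not (0 < alpha <= 1):
        raise ParameterError("alpha must be in (0, 1]")
    records = []
    for i in range(n_reps):
        record, _ = _one_replicate(spec, config, depth, master_seed + i)
        records.append(record)
    zs = np.array([r["z"] for r in records if r["z"] is not None], dtype=float)
    ps = np.array([r["p"] for r in records], dtype=float)
    return CalibrationSummary(
        n_reps=n_reps,
        alpha=alpha,
        rejection_rate=float(np.mean(ps <= alpha)),
        mean_z=float(zs.mean()) if zs.size else float("nan"),
        sd_z=float(zs.std(ddof=1)) if zs.size > 1 else float("nan"),
        records=records if keep_records else [],
    )


def recovery_run(
    spec: SyntheticSpec,
    q_grid: list[int],
    config: NullConfig,
    n_reps: int,
    alpha: float,
    master_seed: int,
    depth: int = 1,
    keep_records: bool = True,
) -> RecoverySummary:
    """Recovery of planted crosstalk along ``q_grid``.

    For each planted strength q, ``n_reps`` replicates are run (paired
    across q: replicate i reuses seed ``master_seed + i``, so the same
    background graph and seed sets are planted at each strength). Reported
    per q: mean excess (observed - expected_null), mean realized planted
    count, relative bias of the excess against it, and the rejection rate
    at alpha (power).
    """
    if not q_grid:
        raise ParameterError("q_grid must be non-empty")
    if sorted(q_grid) != list(q_grid) or len(set(q_grid)) != len(q_grid):
        raise ParameterError("q_grid must be strictly increasing")
    mean_excess, mean_q, rel_bias, power, records = [], [], [], [], []
    for q in q_grid:
        spec_q = replace(spec, planted_q=q)
        excesses, q_addeds, rejections = [], [], []
        for i in range(n_reps):
            record, q_added = _one_replicate(
                spec_q, config, depth, master_seed + i
            )
            record["q"] = q
            records.append(record)
            excesses.append(record["observed"] - record["expected_null"])
            q_addeds.append(q_added)
            rejections.append(record["p"] <= alpha)
        me = float(np.mean(excesses))
        mq = float(np.mean(q_addeds))
        mean_excess.append(me)
        mean_q.append(mq)
        rel_bias.append((me - mq) / mq if mq > 0 else None)
        power.append(float(np.mean(rejections)))
    return RecoverySummary(
        q_grid=list(q_grid),
        mean_excess=mean_excess,
        mean_q_added=mean_q,
        relative_bias=rel_bias,
        power=power,
        alpha=alpha,
        n_reps=n_reps,
        records=records if keep_records else [],
    )
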