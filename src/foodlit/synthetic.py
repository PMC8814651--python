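"""Synthetic respondents, expert panels, and retest replicates.

A latent food-literacy trait theta in [0, 1] jointly drives:

* ordinal (agree/disagree, always/never) answers, via a cumulative-threshold
  model with additive Gaussian noise on theta;
* FFQ intakes, via zero-truncated normals whose means move toward the
  recommended side as ``coupling * theta`` grows — frequency-item answers
  are then *deterministic* bins of the realized intakes, so a nonzero
  priority signal on an eat goal always corresponds to a genuinely
  non-compliant intake;
* diet-quality and self-efficacy proxies, affine in the (de)coupled trait
  plus noise.

``coupling`` in [0, 1] mixes theta with an independent nuisance draw for
each outcome family: at 1 all outcomes share the trait, at 0 the intake,
diet-quality, and self-efficacy channels are mutually independent of the
screener answers.

By default respondents always report a concrete difficulty on the two
situation-choice items (``p_no_difficulty = 0``). Together with the
deterministic intake bins this makes the eat-goal accuracy evaluation exact:
an eat goal can only enter a top-3 list on the strength of a nonzero need
signal.

All randomness fans out from one integer seed into fixed named substreams,
so regeneration is bit-identical and the retest generator can replay the
answer-level noise of the first wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .accuracy import FFQIntake, INTAKE_FIELDS, write_intakes_csv
from .errors import ComputationError
from .instrument import Instrument, bundled_iflt
from .scoring import Response, write_responses_csv

__all__ = [
    "SyntheticCohort",
    "simulate_respondents",
    "simulate_expert_ratings",
    "simulate_retest",
    "DEFAULT_TRAIT_PARAMS",
    "DEFAULT_RETEST_NOISE_SD",
    "analytic_retest_reliability",
]

#: Beta(a, b) latent-trait parameters; a calibration choice placing the mean
#: overall score near the upper-60s band typical of general-population
#: screeners, not a published value.
DEFAULT_TRAIT_PARAMS = (5.0, 2.2)

#: Trait-scale retest noise giving an analytic reliability near 0.72 under
#: the default trait distribution.
DEFAULT_RETEST_NOISE_SD = 0.1

_LIKERT_NOISE_SD = 0.12
_EXTERNAL_NOISE_SD = 0.08

#: intake model per frequency item: (field, mean at theta=0, mean at
#: theta=1, sd). Means cross the recommendation threshold as the trait rises.
_INTAKE_MODELS: dict[str, tuple[str, float, float, float]] = {
    "Q10": ("meat", 260.0, 60.0, 50.0),
    "Q11": ("vegetables", 100.0, 420.0, 60.0),
    "Q12": ("fruit", 60.0, 380.0, 70.0),
    "Q13": ("water", 400.0, 2300.0, 300.0),
    "Q14": ("ultra_processed", 150.0, 20.0, 30.0),
}

#: intake -> option-index bin edges. Ascending ("more is better") items use
#: >= comparisons, descending ones <=; the edge between option indices 4 and
#: 5 sits exactly on the recommendation threshold so that a zero priority
#: score coincides with compliance.
_INTAKE_BINS: dict[str, tuple[str, Sequence[float]]] = {
    "Q10": ("desc", (300.0, 250.0, 200.0, 150.0, 100.0, 30.0)),
    "Q11": ("asc", (60.0, 120.0, 180.0, 240.0, 300.0, 450.0)),
    "Q12": ("asc", (50.0, 100.0, 150.0, 200.0, 250.0, 400.0)),
    "Q13": ("asc", (300.0, 600.0, 900.0, 1200.0, 1500.0, 2200.0)),
    "Q14": ("desc", (200.0, 150.0, 100.0, 75.0, 50.0, 10.0)),
}

_STREAM_NAMES = ("trait", "likert", "situation", "intake", "decouple", "dq", "hese", "energy")


def _streams(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAM_NAMES))
    return dict(zip(_STREAM_NAMES, children))


def _rng(stream: np.random.SeedSequence) -> np.random.Generator:
    return np.random.default_rng(stream)


@dataclass(frozen=True)
class SyntheticCohort:
    responses: tuple[Response, ...]
    intakes: dict[str, FFQIntake]
    hese_scores: np.ndarray
    diet_quality_proxy: np.ndarray
    latent_trait: np.ndarray
    seed: int
    coupling: float
    trait_params: tuple[float, float]
    p_no_difficulty: float
    instrument: Instrument = field(repr=False, default=None)

    @property
    def respondent_ids(self) -> list[str]:
        return [r.respondent_id for r in self.responses]

    def externals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "respondent_id": self.respondent_ids,
                "diet_quality": self.diet_quality_proxy,
                "hese": self.hese_scores,
            }
        )

    def to_csv(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        """Write responses/intakes/externals (+ hidden trait) as CSV files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "responses": out / "responses.csv",
            "intakes": out / "intakes.csv",
            "externals": out / "externals.csv",
            "latent_trait": out / "latent_trait.csv",
        }
        write_responses_csv(paths["responses"], self.instrument, self.responses)
        write_intakes_csv(paths["intakes"], self.intakes)
        self.externals_frame().to_csv(paths["externals"], index=False)
        pd.DataFrame(
            {"respondent_id": self.respondent_ids, "theta": self.latent_trait}
        ).to_csv(paths["latent_trait"], index=False)
        return paths


def _bin_intake(item_id: str, value: float) -> int:
    direction, edges = _INTAKE_BINS[item_id]
    if direction == "asc":
        return int(sum(value >= e for e in edges))
    return int(sum(value <= e for e in edges))


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: float
) -> np.ndarray:
    a = (0.0 - mean) / sd  # truncate at zero
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng)


def _generate_answers(
    inst: Instrument,
    theta: np.ndarray,
    theta_intake: np.ndarray,
    answer_seed: int,
    p_no_difficulty: float,
    prefix: str = "R",
) -> tuple[tuple[Response, ...], dict[str, FFQIntake]]:
    """Generate one wave of answers + intakes from trait vectors.

    All noise draws come from substreams of ``answer_seed`` with shapes that
    depend only on n, so two calls with the same seed but perturbed traits
    share their noise realizations (the retest replay mechanism).
    """
    n = theta.size
    s = _streams(answer_seed)
    rng_likert = _rng(s["likert"])
    rng_situation = _rng(s["situation"])
    rng_intake = _rng(s["intake"])
    rng_energy = _rng(s["energy"])

    width = max(3, len(str(n)))
    ids = [f"{prefix}{i + 1:0{width}d}" for i in range(n)]

    answers: list[dict[str, int]] = [dict() for _ in range(n)]

    # intakes first: frequency answers are deterministic functions of them
    intake_values: dict[str, np.ndarray] = {}
    for item_id, (fld, mean0, mean1, sd) in _INTAKE_MODELS.items():
        mean = mean0 + (mean1 - mean0) * theta_intake
        values = _truncated_normal(rng_intake, mean, sd)
        intake_values[fld] = values
        for i in range(n):
            answers[i][item_id] = _bin_intake(item_id, float(values[i]))
    energy = _truncated_normal(rng_energy, np.full(n, 2100.0), 250.0)

    for item in inst.items:
        if item.item_id in _INTAKE_MODELS:
            continue
        if item.format == "situation_choice":
            concrete = [
                idx
                for idx, o in enumerate(item.options)
                if o.per_goal_ips is None or len(o.per_goal_ips) > 0
            ]
            none_idx = next(
                (
                    idx
                    for idx, o in enumerate(item.options)
                    if o.per_goal_ips is not None and len(o.per_goal_ips) == 0
                ),
                None,
            )
            u = rng_situation.random(n)
            pick = rng_situation.integers(0, len(concrete), n)
            for i in range(n):
                if none_idx is not None and u[i] < p_no_difficulty:
                    answers[i][item.item_id] = none_idx
                else:
                    answers[i][item.item_id] = concrete[int(pick[i])]
        else:
            # ordinal items: evenly spaced thresholds on the noisy trait
            latent = theta + rng_likert.normal(0.0, _LIKERT_NOISE_SD, n)
            idx = np.clip(np.floor(latent * 7).astype(int), 0, 6)
            for i in range(n):
                answers[i][item.item_id] = int(idx[i])

    responses = tuple(
        Response(respondent_id=ids[i], answers=answers[i]) for i in range(n)
    )
    intakes = {
        ids[i]: FFQIntake(
            meat=float(intake_values["meat"][i]),
            vegetables=float(intake_values["vegetables"][i]),
            fruit=float(intake_values["fruit"][i]),
            water=float(intake_values["water"][i]),
            ultra_processed=float(intake_values["ultra_processed"][i]),
            energy=float(energy[i]),
        )
        for i in range(n)
    }
    return responses, intakes


def _mix(coupling: float, theta: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    return coupling * theta + (1.0 - coupling) * nuisance


def simulate_respondents(
    n: int,
    seed: int,
    coupling: float = 1.0,
    trait_params: tuple[float, float] = DEFAULT_TRAIT_PARAMS,
    p_no_difficulty: float = 0.0,
    instrument: Optional[Instrument] = None,
) -> SyntheticCohort:
    """Simulate a cohort of ``n`` respondents with known ground truth."""
    if n < 1:
        raise ComputationError(f"cohort size must be >= 1, got {n}")
    if not 0.0 <= coupling <= 1.0:
        raise ComputationError(f"coupling must be in [0, 1], got {coupling}")
    a, b = trait_params
    if a <= 0 or b <= 0:
        raise ComputationError(f"Beta trait parameters must be positive, got {trait_params}")
    if not 0.0 <= p_no_difficulty <= 1.0:
        raise ComputationError("p_no_difficulty must be in [0, 1]")
    inst = instrument if instrument is not None else bundled_iflt()

    s = _streams(seed)
    theta = _rng(s["trait"]).beta(a, b, n)
    nuisance = _rng(s["decouple"]).beta(a, b, (3, n))

    responses, intakes = _generate_answers(
        inst, theta, _mix(coupling, theta, nuisance[0]), seed, p_no_difficulty
    )
    dq = 100.0 * np.clip(
        _mix(coupling, theta, nuisance[1]) + _rng(s["dq"]).normal(0, _EXTERNAL_NOISE_SD, n),
        0.0,
        1.0,
    )
    hese = 7.0 + 21.0 * np.clip(
        _mix(coupling, theta, nuisance[2]) + _rng(s["hese"]).normal(0, _EXTERNAL_NOISE_SD, n),
        0.0,
        1.0,
    )
    return SyntheticCohort(
        responses=responses,
        intakes=intakes,
        hese_scores=hese,
        diet_quality_proxy=dq,
        latent_trait=theta,
        seed=seed,
        coupling=coupling,
        trait_params=(a, b),
        p_no_difficulty=p_no_difficulty,
        instrument=inst,
    )


def simulate_retest(
    cohort: SyntheticCohort, noise_sd: float, seed: int = 0
) -> tuple[Response, ...]:
    """Second-wave responses from the same cohort.

    ``noise_sd`` is the per-administration noise SD on the trait scale. The
    whole answer machinery is replayed with the first wave's noise
    substreams, so ``noise_sd = 0`` reproduces the original responses bit
    for bit; for ``noise_sd > 0`` the trait is shifted by N(0, 2 * sd^2) —
    the distribution of the *difference* of two independent
    per-administration noises — so the expected test-retest coefficient of
    the overall score approximates the classical
    ``var(theta) / (var(theta) + noise_sd**2)``
    (:func:`analytic_retest_reliability`).
    """
    if noise_sd < 0:
        raise ComputationError("noise_sd must be >= 0")
    n = len(cohort.responses)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perturb = rng.normal(0, np.sqrt(2.0) * noise_sd, n)
    theta2 = np.clip(cohort.latent_trait + perturb, 0.0, 1.0)
    nuisance = _rng(_streams(cohort.seed)["decouple"]).beta(*cohort.trait_params, (3, n))
    responses2, _ = _generate_answers(
        cohort.instrument,
        theta2,
        _mix(cohort.coupling, theta2, nuisance[0]),
        cohort.seed,
        cohort.p_no_difficulty,
    )
    return responses2


def analytic_retest_reliability(
    noise_sd: float, trait_params: tuple[float, float] = DEFAULT_TRAIT_PARAMS
) -> float:
    """Closed-form reliability of an additive-noise retest on the trait
    scale: trait variance / (trait variance + noise variance)."""
    a, b = trait_params
    trait_var = a * b / ((a + b) ** 2 * (a + b + 1))
    return trait_var / (trait_var + noise_sd**2)


def simulate_expert_ratings(
    n_experts: int,
    item_relevance: Union[float, Sequence[float], Mapping[str, float]],
    seed: int,
    item_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Independent 1-4 relevance ratings, experts x items.

    ``item_relevance`` gives each item's probability of a rating >= 3, so
    the expected item content validity index equals the stated relevance.
    """
    if n_experts < 1:
        raise ComputationError("need at least one expert")
    if item_ids is None:
        item_ids = bundled_iflt().item_ids
    if isinstance(item_relevance, Mapping):
        probs = [float(item_relevance[i]) for i in item_ids]
    elif isinstance(item_relevance, (int, float)):
        probs = [float(item_relevance)] * len(item_ids)
    else:
        probs = [float(p) for p in item_relevance]
        if len(probs) != len(item_ids):
            raise ComputationError(
                f"{len(probs)} relevance values for {len(item_ids)} items"
            )
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ComputationError(f"relevance probability {p} outside [0, 1]")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    relevant = rng.random((n_experts, len(item_ids))) < np.asarray(probs)
    high = rng.integers(3, 5, (n_experts, len(item_ids)))  # 3 or 4
    low = rng.integers(1, 3, (n_experts, len(item_ids)))   # 1 or 2
    ratings = np.where(relevant, high, low)
    return pd.DataFrame(
        ratings,
        index=[f"E{j + 1}" for j in range(n_experts)],
        columns=list(item_ids),
    )
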