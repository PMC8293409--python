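"""Synthetic forced-choice experiments with the structure the analysis assumes.

Generates complete sessions — adaptively placed stimuli in [−20, +20]%
(never 0), Bernoulli responses from a four-parameter logistic observer —
so that every downstream stage (QUEST+, Bayesian fits, inference, design
simulation) is testable without any external download.  The default
population matches the design-analysis observer: bias 0, detection
threshold 5%, lapse rate 2%; a study-sized experiment is 11 subjects of
200 trials each (10 blocks of 20).

Reproducibility: one root seed; per-subject generators are spawned as
``default_rng([root_seed, subject_index])`` so adding subjects never
reshuffles earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .psychometric import PFParams, pf_prob, slope_from_threshold
from .quest import QuestPlus

__all__ = [
    "PopulationSpec",
    "SubjectData",
    "sample_subject_params",
    "simulate_session",
    "simulate_experiment",
    "dataset_to_frame",
    "write_trials_csv",
    "read_trials_csv",
    "TRIALS_PER_SUBJECT",
    "TRIALS_PER_BLOCK",
]

TRIALS_PER_SUBJECT = 200
TRIALS_PER_BLOCK = 20

_CSV_COLUMNS = ["subject", "trial", "block", "stimulus_pct", "response"]


@dataclass(frozen=True)
class PopulationSpec:
    """Population the synthetic subjects are drawn from.

    Defaults are the design-analysis observer (bias 0, threshold 5%,
    lapse 2%) with zero between-subject spread; spreads are switched on
    for parameter-recovery studies.
    """

    n_subjects: int = 11
    mean_bias: float = 0.0
    sd_bias: float = 0.0
    mean_threshold: float = 5.0
    sd_threshold: float = 0.0
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sd_bias < 0 or self.sd_threshold < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (self.mean_threshold > 0):
            raise ValueError("mean_threshold must be positive")
        if not (0.0 <= self.lapse < 0.5):
            raise ValueError("lapse must lie in [0, 0.5)")


@dataclass
class SubjectData:
    """One subject's session: trial table plus (for synthetic subjects)
    the generating parameters."""

    subject_id: str
    trials: pd.DataFrame
    true_params: PFParams | None = None

    @property
    def stimuli(self) -> np.ndarray:
        return self.trials["stimulus_pct"].to_numpy(dtype=float)

    @property
    def responses(self) -> np.ndarray:
        """Responses as 1 ("bigger") / 0 ("smaller")."""
        return (self.trials["response"] == "bigger").to_numpy(dtype=int)


def sample_subject_params(spec: PopulationSpec, rng: np.random.Generator) -> PFParams:
    """Draw one subject's psychometric parameters from the population.

    Bias is normal; the detection threshold is positive-truncated normal
    (degenerating to the mean when its SD is 0) and converted to a slope;
    both lapse parameters equal ``spec.lapse``.
    """
    alpha = spec.mean_bias + spec.sd_bias * rng.standard_normal()
    if spec.sd_threshold == 0:
        thr = spec.mean_threshold
    else:
        a = (0.0 - spec.mean_threshold) / spec.sd_threshold
        thr = float(
            stats.truncnorm.rvs(
                a, np.inf, loc=spec.mean_threshold, scale=spec.sd_threshold,
                random_state=rng,
            )
        )
    return PFParams(
        alpha=float(alpha),
        beta=slope_from_threshold(thr),
        gamma=spec.lapse,
        lambda_=spec.lapse,
    )


def _trials_frame(subject_id: str, stimuli, responses) -> pd.DataFrame:
    n = len(stimuli)
    return pd.DataFrame(
        {
            "subject": subject_id,
            "trial": np.arange(1, n + 1),
            "block": 1 + (np.arange(n) // TRIALS_PER_BLOCK),
            "stimulus_pct": np.asarray(stimuli, dtype=float),
            "response": np.where(np.asarray(responses) == 1, "bigger", "smaller"),
        }
    )


def simulate_session(
    params: PFParams,
    design="quest",
    n_trials: int = TRIALS_PER_SUBJECT,
    rng: np.random.Generator | None = None,
    subject_id: str = "s01",
    quest: QuestPlus | None = None,
) -> SubjectData:
    """Simulate one forced-choice session.

    ``design`` is either ``"quest"`` (stimuli placed adaptively by a
    :class:`~vergesize.quest.QuestPlus` engine, a fresh default one unless
    ``quest`` is given) or an explicit sequence of signed % size changes.
    Responses are Bernoulli(pf_prob(params, x)).
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(design, str):
        if design != "quest":
            raise ValueError("design must be 'quest' or a stimulus sequence")
        engine = quest.clone_reset() if quest is not None else QuestPlus()
        stimuli = np.empty(n_trials)
        responses = np.empty(n_trials, dtype=int)
        for t in range(n_trials):
            x = engine.next_stimulus()
            r = int(rng.random() < pf_prob(params, x))
            engine.update(x, r)
            stimuli[t] = x
            responses[t] = r
    else:
        stimuli = np.asarray(design, dtype=float)
        if stimuli.size == 0:
            raise ValueError("fixed design must contain at least one stimulus")
        if np.any(stimuli == 0) or np.any(np.abs(stimuli) > 20):
            raise ValueError("stimuli must lie in [-20, 20] and exclude 0")
        responses = (rng.random(stimuli.size) < pf_prob(params, stimuli)).astype(int)
    return SubjectData(subject_id, _trials_frame(subject_id, stimuli, responses), params)


def simulate_experiment(
    spec: PopulationSpec,
    seed: int,
    design="quest",
    n_trials: int = TRIALS_PER_SUBJECT,
    quest: QuestPlus | None = None,
) -> list[SubjectData]:
    """Simulate a full multi-subject experiment, deterministically seeded.

    Subject ``k`` uses the generator ``default_rng([seed, k])`` for both
    its parameter draw and its responses.
    """
    out = []
    for k in range(spec.n_subjects):
        rng = np.random.default_rng([int(seed), k])
        params = sample_subject_params(spec, rng)
        out.append(
            simulate_session(
                params, design=design, n_trials=n_trials, rng=rng,
                subject_id=f"s{k + 1:02d}", quest=quest,
            )
        )
    return out


# -- trial CSV schema ----------------------------------------------------
# UTF-8, header: subject,trial,block,stimulus_pct,response
# response in {bigger, smaller}; stimulus_pct in [-20, 20] and never 0.


def dataset_to_frame(dataset: list[SubjectData]) -> pd.DataFrame:
    if not dataset:
        return pd.DataFrame(columns=_CSV_COLUMNS)
    return pd.concat([s.trials for s in dataset], ignore_index=True)[_CSV_COLUMNS]


def write_trials_csv(dataset: list[SubjectData], path) -> None:
    dataset_to_frame(dataset).to_csv(path, index=False)


def read_trials_csv(path) -> list[SubjectData]:
    """Read a trial CSV back into per-subject tables, validating every row.

    Malformed rows raise ``ValueError`` naming the offending line number
    (1-based, counting the header as line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        x = row.stimulus_pct
        if not np.isfinite(x) or x == 0 or abs(x) > 20:
            raise ValueError(
                f"{path}, line {i}: stimulus_pct must be in [-20, 20] and non-zero, got {x}"
            )
        if row.response not in ("bigger", "smaller"):
            raise ValueError(
                f"{path}, line {i}: response must be 'bigger' or 'smaller', got {row.response!r}"
            )
    out = []
    for sid, sub in df.groupby("subject", sort=False):
        out.append(SubjectData(str(sid), sub.reset_index(drop=True)))
    return out
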