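"""Synthetic transcripts and cohorts with known generating structure.

The real study population — baseline picture descriptions of individuals
with dementia from the DementiaBank English Pitt corpus — is access
restricted, so every pipeline stage is exercised on synthetic stand-ins:

* **Transcripts** come from a return-probability process: each next token
  either revisits a uniformly chosen earlier token (probability
  ``p_return``) or is drawn uniformly from the vocabulary; after every
  token a new utterance starts with probability ``p_break``.  Raising
  ``p_return`` creates more reciprocal word-to-word paths and hence larger
  strongly connected components, which lets tests manipulate connectedness
  through the full transcript -> graph path rather than by sampling graphs
  directly.  No claim of linguistic realism is made.

* **Cohorts** draw covariates from truncated normals whose default means,
  SDs and ranges match the published summary of the dementia sample
  (:data:`COHORT_DEFAULTS`), then generate severity scores from an
  explicit linear model (controls + fluency aggregate + connectedness)
  plus Gaussian noise, so regression code can be checked against known
  coefficients.  Severity scores are left unclipped by default; clipping
  to instrument ranges is opt-in because it biases coefficient recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from sgdem.cohort_stats import COHORT_COLUMNS, FLUENCY_COLUMNS
from sgdem.errors import CannotImputeError
from sgdem.transcript_io import Transcript

#: Default covariate distributions: (mean, sd, low, high).  These are the
#: published demographic/cognitive/linguistic summaries of the baseline
#: dementia sample the generator emulates.
COHORT_DEFAULTS: dict[str, tuple[float, float, float, float]] = {
    "age": (71.93, 8.70, 50.0, 88.0),
    "education": (12.37, 2.95, 6.0, 20.0),
    "hdrs": (5.93, 3.55, 0.0, 16.0),
    "semantic_fluency": (9.11, 4.66, 2.0, 22.0),
    "phonemic_fluency": (6.74, 4.23, 0.0, 19.0),
    "mean_lcc": (57.07, 22.85, 14.0, 151.0),
    "mean_lsc": (35.78, 21.91, 1.0, 117.0),
}

#: Mean years between symptom onset and assessment (age 71.93 - onset
#: 68.26); onset age is generated as age minus a non-negative duration so
#: the onset <= age invariant holds row-wise.
ONSET_LAG_MEAN = 71.93 - 68.26
ONSET_LAG_SD = 2.0

#: Generating coefficients for each severity outcome, in the order
#: (intercept, hdrs, onset_age, education, fluency_z, connectedness).
#: Defaults follow the published LCC-model estimates.
SEVERITY_COEFFS: dict[str, tuple[float, ...]] = {
    "mmse": (17.08, 0.02, -0.04, 0.27, 1.59, 0.04),
    "mdrs": (100.25, 0.13, -0.06, 1.11, 4.90, 0.09),
    "bds": (8.58, 0.40, -0.02, -0.18, -0.34, -0.01),
}

#: Target model R^2 used to derive noise SDs when none are given.  MMSE
#: and MDRS follow the published variance explained; the BDS model was not
#: significant in the source analysis and no R^2 was reported, so a
#: modest 0.15 is used.
TARGET_R2: dict[str, float] = {"mmse": 0.44, "mdrs": 0.61, "bds": 0.15}

#: Instrument score ranges, applied only when clipping is requested.
SCORE_RANGES = {"mmse": (0, 30), "mdrs": (0, 144), "bds": (0, 28)}


@dataclass(frozen=True)
class TranscriptGenParams:
    """Parameters of the return-probability token process."""

    vocab_size: int = 60
    n_tokens: int = 120
    p_return: float = 0.5
    p_break: float = 0.1
    seed: int = 0
    without_replacement: bool = False

    def __post_init__(self):
        if self.vocab_size < 1 or self.n_tokens < 1:
            raise ValueError("vocab_size and n_tokens must be positive")
        for p in (self.p_return, self.p_break):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.without_replacement and self.vocab_size < self.n_tokens:
            raise ValueError(
                "without_replacement needs vocab_size >= n_tokens"
            )


def generate_transcript(
    params: TranscriptGenParams, participant_id: str = "synthetic"
) -> Transcript:
    """Draw one transcript from the return-probability process.

    Deterministic given ``params`` (including the seed).  With
    ``without_replacement=True`` fresh draws never repeat a vocabulary
    item, so ``p_return=0`` yields an all-distinct token sequence.
    """
    rng = np.random.default_rng(params.seed)
    width = len(str(params.vocab_size - 1))
    vocab = [f"w{i:0{width}d}" for i in range(params.vocab_size)]
    unused = list(range(params.vocab_size))

    tokens: list[str] = []
    utterances: list[list[str]] = [[]]
    for _ in range(params.n_tokens):
        if tokens and rng.random() < params.p_return:
            tok = tokens[rng.integers(len(tokens))]
        elif params.without_replacement:
            j = rng.integers(len(unused))
            tok = vocab[unused.pop(j)]
        else:
            tok = vocab[rng.integers(params.vocab_size)]
        tokens.append(tok)
        utterances[-1].append(tok)
        if rng.random() < params.p_break:
            utterances.append([])
    utterances = [u for u in utterances if u]
    return Transcript(participant_id=participant_id, utterances=utterances)


@dataclass(frozen=True)
class CohortGenParams:
    """Parameters of the synthetic cohort generator.

    ``covariates`` maps column -> (mean, sd, low, high) for truncated
    normal draws; ``coefficients`` maps outcome -> generating linear-model
    coefficients over (intercept, hdrs, onset_age, education, fluency_z,
    connectedness); ``noise_sd`` overrides the noise derived from
    ``target_r2`` when given.  ``connectedness_measure`` names which
    column enters the generating model.
    """

    n: int = 128
    seed: int = 0
    covariates: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(COHORT_DEFAULTS)
    )
    coefficients: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(SEVERITY_COEFFS)
    )
    target_r2: dict[str, float] = field(default_factory=lambda: dict(TARGET_R2))
    noise_sd: dict[str, float] | None = None
    missing_rate: float = 0.0
    connectedness_measure: str = "lcc"
    clip_scores: bool = False
    from_transcripts: bool = False
    transcript_params: TranscriptGenParams = TranscriptGenParams()

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("n must be at least 10")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, n: int
) -> np.ndarray:
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(
        a, b, loc=mean, scale=sd, size=n, random_state=rng
    )


def generate_cohort(
    params: CohortGenParams = CohortGenParams(),
) -> tuple[pd.DataFrame, list[Transcript] | None]:
    """Generate a cohort table (and optionally per-participant transcripts).

    Covariates are truncated-normal draws; connectedness is either drawn
    directly on the published scale (default) or computed by the windowed
    pipeline from generated transcripts (``from_transcripts=True``, in
    which case per-participant ``p_return`` varies uniformly to spread
    connectedness).  Severity outcomes follow the generating linear model
    with Gaussian noise whose SD is either given per outcome or derived
    from ``target_r2`` via ``noise_sd = sd(lp) * sqrt((1-R2)/R2)``.

    Returns ``(cohort, transcripts)``; ``transcripts`` is None unless
    ``from_transcripts`` was set.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    cov = params.covariates

    df = pd.DataFrame({"participant_id": [f"S{i:04d}" for i in range(n)]})
    df["age"] = _truncnorm(rng, *cov["age"], n)
    df["education"] = _truncnorm(rng, *cov["education"], n)
    lag = _truncnorm(rng, ONSET_LAG_MEAN, ONSET_LAG_SD, 0.0, 15.0, n)
    df["onset_age"] = df["age"] - lag
    df["hdrs"] = _truncnorm(rng, *cov["hdrs"], n)
    df["semantic_fluency"] = _truncnorm(rng, *cov["semantic_fluency"], n)
    df["phonemic_fluency"] = _truncnorm(rng, *cov["phonemic_fluency"], n)

    transcripts: list[Transcript] | None = None
    if params.from_transcripts:
        from sgdem.windowing import WindowSpec, windowed_connectedness

        transcripts = []
        lcc, lsc = np.empty(n), np.empty(n)
        child_seeds = rng.integers(0, 2**31 - 1, size=n)
        p_returns = rng.uniform(0.15, 0.85, size=n)
        for i in range(n):
            tp = replace(
                params.transcript_params,
                p_return=float(p_returns[i]),
                seed=int(child_seeds[i]),
            )
            t = generate_transcript(tp, participant_id=df["participant_id"][i])
            transcripts.append(t)
            wc = windowed_connectedness(t, WindowSpec())
            lcc[i], lsc[i] = wc.mean_lcc, wc.mean_lsc
        df["mean_lcc"], df["mean_lsc"] = lcc, lsc
    else:
        df["mean_lcc"] = _truncnorm(rng, *cov["mean_lcc"], n)
        df["mean_lsc"] = np.minimum(
            _truncnorm(rng, *cov["mean_lsc"], n), df["mean_lcc"]
        )

    # fluency aggregate and connectedness as they enter the generating model
    z = np.zeros(n)
    for col in FLUENCY_COLUMNS:
        x = df[col].to_numpy()
        z = z + (x - x.mean()) / x.std(ddof=1)
    meas_col = {"lcc": "mean_lcc", "lsc": "mean_lsc"}[params.connectedness_measure]
    design = np.column_stack(
        [
            np.ones(n),
            df["hdrs"],
            df["onset_age"],
            df["education"],
            z,
            df[meas_col],
        ]
    )
    for outcome in ("mmse", "mdrs", "bds"):
        beta = np.asarray(params.coefficients[outcome], float)
        lp = design @ beta
        if params.noise_sd is not None and outcome in params.noise_sd:
            sd_noise = params.noise_sd[outcome]
        else:
            r2 = params.target_r2[outcome]
            sd_noise = float(np.std(lp, ddof=1) * np.sqrt((1 - r2) / r2))
        y = lp + rng.normal(0.0, sd_noise, size=n)
        if params.clip_scores:
            lo, hi = SCORE_RANGES[outcome]
            y = np.clip(np.round(y), lo, hi)
        df[outcome] = y

    df = df[COHORT_COLUMNS]
    if params.missing_rate > 0:
        df = apply_missingness(
            df, params.missing_rate, seed=int(rng.integers(2**31 - 1))
        )
    return df, transcripts


def apply_missingness(
    cohort: pd.DataFrame, rate: float, seed: int
) -> pd.DataFrame:
    """Delete fluency cells completely at random at the given rate.

    Each semantic/phonemic fluency cell is independently set missing with
    probability ``rate``.  Deterministic given the seed.  Raises
    :class:`CannotImputeError` if the deletion would leave fewer than 3
    observed values in either variable (the downstream imputer's minimum).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random((len(out), len(FLUENCY_COLUMNS))) < rate
    for j, col in enumerate(FLUENCY_COLUMNS):
        n_left = int((~mask[:, j]).sum())
        if n_left < 3:
            raise CannotImputeError(
                f"missing rate {rate} would leave {n_left} observed "
                f"values in {col}"
            )
        out.loc[mask[:, j], col] = np.nan
    return out
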