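"""Exception types raised across the pipeline."""

from __future__ import annotations


class SgdemError(Exception):
    """Base class for all pipeline errors."""


class EmptyTranscriptError(SgdemError):
    """A transcript source yielded no utterances (or none for the speaker)."""


class EmptyGraphError(SgdemError):
    """A graph operation was asked for on zero tokens.

    Transcripts below the window length are excluded upstream, so an empty
    input here signals pipeline misuse rather than a data condition.
    """


class TranscriptTooShortError(SgdemError):
    """Transcript has fewer tokens than one window; excluded from analysis.

    Mirrors the cohort exclusion rule for picture descriptions containing
    fewer than 30 words.  Carries the participant id and token count so the
    exclusion can be logged in machine-readable form.
    """

    def __init__(self, participant_id: str, n_tokens: int, window_length: int):
        self.participant_id = participant_id
        self.n_tokens = n_tokens
        self.window_length = window_length
        super().__init__(
            f"transcript too short: participant {participant_id!r} has "
            f"{n_tokens} tokens < window length {window_length}"
        )


class DegenerateFluencyError(SgdemError):
    """A fluency measure has zero sample SD; z-scores are undefined."""


class CannotImputeError(SgdemError):
    """A variable cannot be imputed (fully missing or too few observed)."""


class CollinearPredictorsError(SgdemError):
    """The regression design matrix is rank deficient."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"collinear predictors: {', '.join(columns)}")
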