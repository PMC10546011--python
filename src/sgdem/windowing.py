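"""Moving-window verbosity control for speech-graph attributes.

Longer narratives mechanically accumulate larger graphs, so raw LCC/LSC
confound connectedness with verbosity.  The control: slide a fixed-length
window (default 30 words) over the concatenated token sequence with a
fixed step (default 3 words, i.e. 90% overlap between consecutive
windows), build one graph per window — still respecting utterance
boundaries for edges — and report the grand mean of each attribute over
all complete windows.  Trailing tokens that cannot fill a complete window
are dropped, never padded.

Transcripts shorter than one window cannot be analyzed and are excluded,
mirroring the cohort rule that picture descriptions with fewer than 30
words are removed from the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from sgdem.errors import TranscriptTooShortError
from sgdem.speech_graph import ConnectednessResult, build_graph, connectedness
from sgdem.transcript_io import Transcript


@dataclass(frozen=True)
class WindowSpec:
    """Fixed-length moving window: ``window_length`` tokens, ``step`` stride."""

    window_length: int = 30
    step: int = 3

    def __post_init__(self):
        if self.window_length < 1 or self.step < 1:
            raise ValueError("window_length and step must be positive")
        if self.step > self.window_length:
            raise ValueError("step must not exceed window_length")

    @property
    def overlap_fraction(self) -> float:
        """Token overlap between consecutive windows; 0.9 at defaults."""
        return (self.window_length - self.step) / self.window_length


@dataclass
class WindowedConnectedness:
    """Per-window attributes and their grand means for one transcript."""

    participant_id: str
    per_window: list[ConnectednessResult]
    mean_lcc: float
    mean_lsc: float

    @property
    def n_windows(self) -> int:
        return len(self.per_window)


def enumerate_windows(n_tokens: int, spec: WindowSpec = WindowSpec()) -> list[tuple[int, int]]:
    """Half-open 0-based token spans ``[k*step, k*step + window_length)``.

    Only complete windows are emitted.  Raises
    :class:`TranscriptTooShortError` when ``n_tokens < window_length``.
    """
    if n_tokens < spec.window_length:
        raise TranscriptTooShortError("<unknown>", n_tokens, spec.window_length)
    n_win = (n_tokens - spec.window_length) // spec.step + 1
    return [
        (k * spec.step, k * spec.step + spec.window_length) for k in range(n_win)
    ]


def windowed_connectedness(
    transcript: Transcript, spec: WindowSpec = WindowSpec()
) -> WindowedConnectedness:
    """Grand-mean LCC/LSC of a transcript under the moving window.

    Windows are defined on the concatenated token sequence and may span
    several utterances; edge construction inside each window still
    respects the original utterance boundaries.

    Raises
    ------
    TranscriptTooShortError
        If the transcript has fewer tokens than one window.  The error
        carries the participant id and token count for the exclusion log.
    """
    flat: list[tuple[str, int]] = [
        (tok, ui)
        for ui, utt in enumerate(transcript.utterances)
        for tok in utt
    ]
    try:
        spans = enumerate_windows(len(flat), spec)
    except TranscriptTooShortError:
        raise TranscriptTooShortError(
            transcript.participant_id, len(flat), spec.window_length
        ) from None

    results: list[ConnectednessResult] = []
    for start, end in spans:
        window = flat[start:end]
        # regroup into utterance runs so no edge crosses a boundary
        utts: list[list[str]] = []
        prev_ui = None
        for tok, ui in window:
            if ui != prev_ui:
                utts.append([])
                prev_ui = ui
            utts[-1].append(tok)
        results.append(connectedness(build_graph(utts)))

    mean_lcc = sum(r.lcc_nodes for r in results) / len(results)
    mean_lsc = sum(r.lsc_nodes for r in results) / len(results)
    return WindowedConnectedness(
        participant_id=transcript.participant_id,
        per_window=results,
        mean_lcc=mean_lcc,
        mean_lsc=mean_lsc,
    )


def analyze_transcripts(
    transcripts: list[Transcript], spec: WindowSpec = WindowSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed connectedness for a batch, with a machine-readable exclusion log.

    Returns
    -------
    results
        One row per analyzable participant: ``participant_id, n_tokens,
        n_windows, mean_lcc, mean_lsc``.
    exclusions
        One row per excluded participant: ``participant_id, n_tokens,
        reason`` (currently always the too-few-words rule).
    """
    rows, excl = [], []
    for t in transcripts:
        try:
            wc = windowed_connectedness(t, spec)
        except TranscriptTooShortError as e:
            excl.append(
                {
                    "participant_id": e.participant_id,
                    "n_tokens": e.n_tokens,
                    "reason": f"fewer than {spec.window_length} words",
                }
            )
            continue
        rows.append(
            {
                "participant_id": t.participant_id,
                "n_tokens": t.n_tokens,
                "n_windows": wc.n_windows,
                "mean_lcc": wc.mean_lcc,
                "mean_lsc": wc.mean_lsc,
            }
        )
    results = pd.DataFrame(
        rows, columns=["participant_id", "n_tokens", "n_windows", "mean_lcc", "mean_lsc"]
    )
    exclusions = pd.DataFrame(excl, columns=["participant_id", "n_tokens", "reason"])
    return results, exclusions
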