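"""Read CHAT and plain-text picture-description transcripts.

A transcript is an ordered list of utterances, each an ordered list of
lowercase word tokens.  The utterance boundary is meaningful: the graph
builder never draws an edge across it, following the transcription
convention that speech following an interruption is placed on a new line.

The CHAT reader is deliberately minimal: it selects one speaker's main
tier, skips dependent tiers (``%mor``, ``%gra``, ...), and strips CHAT
markup codes while keeping the words the speaker actually produced —
including retraced/repeated material, because word repetition is exactly
what the strongly-connected-component measure responds to.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from sgdem.errors import EmptyTranscriptError

#: Characters stripped from token edges (internal apostrophes/hyphens kept).
PUNCT_STRIP = ".,!?;:\"()[]{}«»“”…‡„+-_/\\<>~^|"

#: Filled pauses removable via ``drop_fillers``.
FILLERS = frozenset({"uh", "um", "er", "ah", "eh", "hm", "hmm", "mhm", "uhm"})


@dataclass(frozen=True)
class NormalizationOptions:
    """Token-cleaning policy.

    drop_fillers
        Remove filled pauses (uh, um, ...).  Off by default: fillers are
        words the speaker produced.
    lemmatizer
        Optional callable mapping a surface token to a lemma.  None by
        default; graphs are built over surface forms.
    punct_strip
        Characters stripped from both ends of each raw token.  Internal
        characters (the apostrophe in "boy's") are retained.
    """

    drop_fillers: bool = False
    lemmatizer: Callable[[str], str] | None = None
    punct_strip: str = PUNCT_STRIP


DEFAULT_OPTIONS = NormalizationOptions()


@dataclass
class Transcript:
    """One participant's utterance-segmented token sequence."""

    participant_id: str
    utterances: list[list[str]] = field(default_factory=list)

    @property
    def n_tokens(self) -> int:
        return sum(len(u) for u in self.utterances)

    def tokens(self) -> list[str]:
        """All tokens in spoken order, utterance boundaries flattened."""
        return [tok for utt in self.utterances for tok in utt]

    def __len__(self) -> int:
        return self.n_tokens


def normalize_tokens(
    raw: Iterable[str], options: NormalizationOptions = DEFAULT_OPTIONS
) -> list[str]:
    """Case-fold, strip edge punctuation and drop emptied strings.

    Total function: any list of strings is accepted; tokens that normalize
    to the empty string (pure punctuation such as "...") are dropped.
    Idempotent by construction.
    """
    out: list[str] = []
    for tok in raw:
        t = tok.lower().strip(options.punct_strip + " \t\r\n\f\v")
        if not t:
            continue
        if options.drop_fillers and t in FILLERS:
            continue
        if options.lemmatizer is not None:
            t = options.lemmatizer(t)
            if not t:
                continue
        out.append(t)
    return out


def _utterances_from_lines(
    lines: Iterable[str], options: NormalizationOptions
) -> list[list[str]]:
    utts = []
    for line in lines:
        toks = normalize_tokens(line.split(), options)
        if toks:
            utts.append(toks)
    return utts


def read_plaintext(
    path: str | Path,
    participant_id: str | None = None,
    options: NormalizationOptions = DEFAULT_OPTIONS,
) -> Transcript:
    """Read a UTF-8 plain-text transcript, one utterance per line.

    Line breaks model interruption boundaries; blank lines are ignored.
    Raises :class:`EmptyTranscriptError` if no line yields tokens.
    """
    path = Path(path)
    utts = _utterances_from_lines(
        path.read_text(encoding="utf-8").splitlines(), options
    )
    if not utts:
        raise EmptyTranscriptError(f"no utterances in {path}")
    pid = participant_id if participant_id is not None else path.stem
    return Transcript(participant_id=pid, utterances=utts)


def write_plaintext(transcript: Transcript, path: str | Path) -> None:
    """Write one utterance per line; inverse of :func:`read_plaintext`."""
    Path(path).write_text(
        "".join(" ".join(u) + "\n" for u in transcript.utterances),
        encoding="utf-8",
    )


# --- CHAT (.cha) ----------------------------------------------------------

# Markup removed wholesale: [...] code groups, +... terminators, (.) pauses.
_BRACKET_RE = re.compile(r"\[[^\]]*\]")
_PAUSE_RE = re.compile(r"\(\.+\)")
_PLUS_CODE_RE = re.compile(r"(?<!\S)\+\S*")
_UNINTELLIGIBLE = {"xxx", "xx", "yyy", "www", "0"}


def _strip_chat_markup(text: str) -> str:
    """Remove CHAT codes from a main-tier line, keeping spoken words.

    Retracing/repetition groups ``<the the> [/]`` lose their delimiters but
    keep their words.  Shortenings like ``(be)cause`` are expanded.  Filler
    prefixes ``&-`` and ``&=`` event codes are handled: ``&-uh`` keeps the
    word, ``&=laughs`` and phonological fragments ``&+fr`` are dropped.
    """
    text = _BRACKET_RE.sub(" ", text)
    text = _PAUSE_RE.sub(" ", text)
    text = _PLUS_CODE_RE.sub(" ", text)
    words = []
    for w in text.split():
        w = w.replace("<", " ").replace(">", " ").strip()
        for piece in w.split():
            if piece.startswith(("&=", "&+", "&*")):
                continue  # events, fragments, interposed words
            if piece.startswith("&-") or piece.startswith("&"):
                piece = piece.lstrip("&-")
            # (be)cause -> because; drop @-suffixed form markers' tail
            piece = piece.replace("(", "").replace(")", "")
            piece = piece.split("@")[0]
            if not piece or piece in _UNINTELLIGIBLE:
                continue
            words.append(piece)
    return " ".join(words)


def read_chat(
    path: str | Path,
    speaker_code: str = "PAR",
    options: NormalizationOptions = DEFAULT_OPTIONS,
) -> Transcript:
    """Read one speaker's main-tier utterances from a CHAT (.cha) file.

    Parameters
    ----------
    path
        CHAT-conformant file.  Header (``@``) and dependent (``%``) tiers
        are skipped; main tiers of other speakers are skipped.
    speaker_code
        Three-letter speaker code of the target main tier (``*PAR:`` by
        default — the participant tier in DementiaBank transcripts).

    Raises
    ------
    EmptyTranscriptError
        If the file contains no (non-empty) utterances for the speaker.
    """
    path = Path(path)
    target = f"*{speaker_code}:"
    lines: list[str] = []
    current: str | None = None
    for raw_line in path.read_text(encoding="utf-8").splitlines():
        if raw_line.startswith(("\t", " ")) and current is not None:
            current += " " + raw_line.strip()  # continuation of main tier
            continue
        if current is not None:
            lines.append(current)
            current = None
        if raw_line.startswith(target):
            current = raw_line[len(target):].strip()
    if current is not None:
        lines.append(current)

    utts = _utterances_from_lines(
        (_strip_chat_markup(line) for line in lines), options
    )
    if not utts:
        raise EmptyTranscriptError(
            f"no utterances for speaker {speaker_code!r} in {path}"
        )
    return Transcript(participant_id=path.stem, utterances=utts)


def tokens_to_json(transcript: Transcript) -> str:
    """Serialize utterance-segmented tokens for the CLI `tokenize` command."""
    return json.dumps(
        {
            "participant_id": transcript.participant_id,
            "n_tokens": transcript.n_tokens,
            "utterances": transcript.utterances,
        },
        indent=2,
    )


def read_transcript(
    path: str | Path,
    speaker_code: str = "PAR",
    options: NormalizationOptions = DEFAULT_OPTIONS,
) -> Transcript:
    """Dispatch on extension: ``.cha`` -> CHAT reader, else plain text."""
    p = Path(path)
    if p.suffix.lower() == ".cha":
        return read_chat(p, speaker_code=speaker_code, options=options)
    return read_plaintext(p, options=options)
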