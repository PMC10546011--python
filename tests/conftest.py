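from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _brute importable

from sgdem.synthetic_data import CohortGenParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default (published-summary) parameters."""
    cohort, _ = generate_cohort(CohortGenParams(n=128, seed=202))
    return cohort


@pytest.fixture
def chat_file(tmp_path) -> Path:
    """Small CHAT transcript with participant + investigator tiers."""
    text = (
        "@UTF8\n"
        "@Begin\n"
        "@Participants:\tPAR Participant, INV Investigator\n"
        "@ID:\teng|pitt|PAR|71;|male|||Participant||\n"
        "*INV:\tokay tell me what you see .\n"
        "%mor:\tco|okay v|tell pro|me pro:int|what pro|you v|see .\n"
        "*PAR:\twell the boy .\n"
        "%mor:\tco|well det|the n|boy .\n"
        "*PAR:\tis falling\n"
        "\toff the stool .\n"
        "*PAR:\t<the the> [/] the boy &-uh takes [x 2] a cookie (be)cause &=laughs xxx .\n"
        "@End\n"
    )
    p = tmp_path / "synthetic_pitt.cha"
    p.write_text(text, encoding="utf-8")
    return p
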