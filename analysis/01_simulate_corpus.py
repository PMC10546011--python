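"""Simulate a picture-description corpus and its cohort table.

Stands in for the access-restricted DementiaBank Pitt baseline sample:
128 synthetic participants each get a transcript from the
return-probability process (per-participant return probability varied to
spread connectedness), covariates drawn at the published cohort summary
values, severity scores from the generating linear model, and 25% MCAR
missingness in the two fluency measures.  Three extra transcripts with
fewer than 30 words are planted to exercise the exclusion rule downstream.

Writes results/sim/transcripts/*.txt, results/sim/cohort.csv and a
params.json manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

from sgdem.cohort_stats import write_cohort_csv
from sgdem.synthetic_data import (
    COHORT_DEFAULTS,
    SEVERITY_COEFFS,
    TARGET_R2,
    CohortGenParams,
    TranscriptGenParams,
    generate_cohort,
    generate_transcript,
)
from sgdem.transcript_io import write_plaintext

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    params = CohortGenParams(
        n=128, seed=SEED, missing_rate=0.25, from_transcripts=True
    )
    cohort, transcripts = generate_cohort(params)

    tdir = OUT / "transcripts"
    tdir.mkdir(parents=True, exist_ok=True)
    assert transcripts is not None
    for t in transcripts:
        write_plaintext(t, tdir / f"{t.participant_id}.txt")
    # planted too-short narratives (excluded at baseline in the real corpus)
    for i, n_tok in enumerate((8, 17, 29)):
        short = generate_transcript(
            TranscriptGenParams(n_tokens=n_tok, seed=900 + i),
            participant_id=f"SHORT{i}",
        )
        write_plaintext(short, tdir / f"{short.participant_id}.txt")

    write_cohort_csv(cohort, OUT / "cohort.csv")
    (OUT / "params.json").write_text(
        json.dumps(
            {
                "seed": SEED,
                "n": params.n,
                "missing_rate": params.missing_rate,
                "planted_short_transcripts": 3,
                "covariate_defaults": COHORT_DEFAULTS,
                "generating_coefficients": SEVERITY_COEFFS,
                "target_r2": TARGET_R2,
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    n_missing = int(
        cohort[["semantic_fluency", "phonemic_fluency"]].isna().sum().sum()
    )
    print(f"wrote {len(transcripts)} transcripts (+3 planted short) to {tdir}")
    print(
        f"cohort.csv: {len(cohort)} participants, {n_missing} missing "
        f"fluency cells ({n_missing / (2 * len(cohort)):.0%} of cells)"
    )


if __name__ == "__main__":
    main()
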