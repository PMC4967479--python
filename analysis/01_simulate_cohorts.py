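#!/usr/bin/env python
"""Simulate the study cohorts used by the downstream analysis scripts.

Writes one fixture bundle (FASTA + alignment-record TSV + SAM + ground
truth) per genetic-code preset under results/sim/.  The ambiguous-code
cohort carries the study-like conditions: 0.3x proximal suppression of
sense-"stop" codons and mostly readthrough-free footprints.
"""

from pathlib import Path

from ambicode.simulate import SimConfig, write_fixture_bundle

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"

PRESETS = {
    "standard": SimConfig(seed=101, n_transcripts=400, code="standard"),
    "uar-q": SimConfig(seed=102, n_transcripts=400, code="uar-q"),
    "uga-w": SimConfig(seed=103, n_transcripts=400, code="uga-w"),
    "uga-c": SimConfig(seed=104, n_transcripts=400, code="uga-c"),
    "ambiguous-cmag": SimConfig(
        seed=105,
        n_transcripts=800,
        code="ambiguous-cmag",
        depletion_factor=0.3,
        readthrough_rate=0.135,
        readthrough_zero_fraction=0.9,
    ),
}


def main() -> None:
    for name, cfg in PRESETS.items():
        outdir = OUT / name
        paths = write_fixture_bundle(cfg, outdir)
        print(f"{name}: {cfg.n_transcripts} transcripts -> {outdir}")
        for kind, path in paths.items():
            print(f"  {kind}: {path.name} ({path.stat().st_size // 1024} kB)")


if __name__ == "__main__":
    main()
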