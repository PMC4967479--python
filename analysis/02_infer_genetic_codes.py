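#!/usr/bin/env python
"""Infer the genetic code of every simulated cohort and compare to truth.

For each preset bundle from 01_simulate_cohorts.py: filter the alignment
records (conditional e-value < 1e-10, column conservation >= 50%), build
the 64x20 codon/amino-acid matrix, call the code from per-codon shares, and
write the prediction table plus the per-amino-acid logo matrix.  Prints the
number of correctly recovered codons per cohort.
"""

from pathlib import Path

from ambicode.codes import BUILTIN_CODES
from ambicode.inference import (
    accumulate_matrix,
    compare_to_code,
    export_logo_matrix,
    filter_records,
    normalize_matrix,
    predict_code,
    read_records_tsv,
    write_prediction,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for bundle in sorted((ROOT / "sim").iterdir()):
        records_path = bundle / "alignment_records.tsv"
        if not records_path.exists():
            continue
        name = bundle.name
        records = read_records_tsv(records_path)
        kept, report = filter_records(records)
        matrix = accumulate_matrix(kept)
        prediction = predict_code(matrix)
        outdir = ROOT / "infer_code" / name
        outdir.mkdir(parents=True, exist_ok=True)
        write_prediction(prediction, outdir / "code_prediction.tsv", outdir / "code_prediction.json")
        export_logo_matrix(normalize_matrix(matrix, "per_amino_acid"), outdir / "logo_matrix.tsv")
        mismatches = compare_to_code(prediction, BUILTIN_CODES[name])
        print(
            f"{name}: retained {report.n_retained}/{report.n_input} records; "
            f"{64 - len(mismatches)}/64 codons correct"
            + (f" (mismatches: {mismatches})" if mismatches else "")
        )


if __name__ == "__main__":
    main()
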