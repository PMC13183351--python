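"""Generate the paired synthetic registers and report their descriptives.

Builds the default CDS-like / ADS-like register pair (shared lexicon and
case paradigm; the CDS-like side calibrated 0.79 bits lower in A-role and
0.55 bits lower in P-role lexical entropy), generates both corpora, and
writes them as JSONL together with the entropy descriptives table.
"""

import argparse
from pathlib import Path

import pandas as pd

from roleprobe import pipeline
from roleprobe.corpus import apply_dataset_filters, write_role_dataset
from roleprobe.entropy import describe_dataset
from roleprobe.synth import generate_corpus


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=6000)
    ap.add_argument("--outdir", type=Path, default=Path("results/01_simulate"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cds_spec, ads_spec = pipeline.default_register_pair("russian_like")
    rows = []
    for spec in (cds_spec, ads_spec):
        ds = generate_corpus(spec, args.n,
                             seed=pipeline.substream(args.seed,
                                                     f"corpus:{spec.label}"))
        ds = apply_dataset_filters(ds)
        write_role_dataset(ds, args.outdir / f"{spec.label.lower()}.jsonl")
        rep = describe_dataset(ds, spec.paradigm)
        rows.extend(rep.to_rows())
        print(f"{spec.label}: {len(ds.utterances)} utterances, "
              f"{ds.total_tokens()} tokens, "
              f"A-entropy {rep.argument_entropy['A']:.2f} bits, "
              f"P-entropy {rep.argument_entropy['P']:.2f} bits")
    table = pd.DataFrame(rows)
    table.to_csv(args.outdir / "entropy.csv", index=False)
    piv = table.pivot_table(index=["type", "role"], columns="register",
                            values="entropy_bits")
    print("\nEntropy (bits):")
    print(piv.round(3).to_string())
    gap = piv["CDS"] - piv["ADS"]
    print("\nCDS - ADS argument-entropy gap per role "
          "(design targets: A -0.79, P -0.55):")
    print(gap.loc["argument"].round(3).to_string())


if __name__ == "__main__":
    main()
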