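"""Filter taxa on the pooled cohorts and clr-normalize.

Keeps species seen at >=2 reads in >=10% of samples with mean relative
abundance >=0.001%, adds a pseudocount of 1, applies the centered log-ratio
transform and removes per-cohort mean shifts.  Writes the clr matrix and a
per-taxon audit of the filter.
"""

import argparse
from pathlib import Path

import pandas as pd

from microsurv import batch_center, clr_transform, filter_taxa
from microsurv import io as msio


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", default="results/analysis/data")
    ap.add_argument("--outdir", default="results/analysis")
    args = ap.parse_args()
    data = Path(args.datadir)
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    counts = pd.concat([msio.read_counts(p)
                        for p in sorted(data.glob("*_counts.tsv"))])
    meta = pd.concat([msio.read_metadata(p)
                      for p in sorted(data.glob("*_metadata.tsv"))])
    filtered, audit = filter_taxa(counts)
    clr = batch_center(clr_transform(filtered), meta.loc[filtered.index,
                                                         "cohort"])
    msio.write_matrix(clr.values, out / "clr.tsv")
    msio.write_matrix(audit, out / "filter_audit.tsv", index_name="taxon")

    removed = audit.loc[~audit["kept"], "removal_reason"].value_counts()
    print(f"retained {filtered.shape[1]} of {counts.shape[1]} taxa")
    for reason, n in removed.items():
        print(f"  removed by {reason}: {n}")
    print(f"clr row-sum |max| = "
          f"{clr.values.sum(axis=1).abs().max():.2e} (should be ~0)")


if __name__ == "__main__":
    main()
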