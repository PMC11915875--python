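"""Microbial Risk Scores and their survival associations.

Builds the per-outcome MRS (weighted sum of selected species' clr
abundances, weights = pooled log-HRs, z-scored over the combined cohorts),
fits covariate-adjusted Cox models per cohort pooled by meta-analysis,
draws the median-split Kaplan-Meier comparison, and re-runs the Cox model
within smoking and stage strata.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from microsurv import build_mrs, cox_mrs, km_logrank, stratified_rerun
from microsurv import io as msio
from microsurv.survival_meta import SelectionResult


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", default="results/analysis/data")
    ap.add_argument("--outdir", default="results/analysis")
    args = ap.parse_args()
    data, out = Path(args.datadir), Path(args.outdir)

    clr = msio.read_matrix(out / "clr.tsv")
    meta = pd.concat([msio.read_metadata(p)
                      for p in sorted(data.glob("*_metadata.tsv"))])
    meta = meta.loc[clr.index]

    summary = {}
    for oc, tag in (("os", "Mortality"), ("rfs", "Relapse")):
        assoc = msio.read_matrix(out / f"associations_{oc}.tsv")
        freq = assoc["O_j"]
        sel = SelectionResult(freq, assoc["selected"].astype(bool), 100,
                              0.9, 0.05, 0.60, oc)
        if not sel.selected_taxa:
            print(f"[{oc}] nothing selected; skipping MRS")
            continue
        mrs = build_mrs(clr, sel, assoc, tag)
        pooled, per_cohort = cox_mrs(mrs, meta, oc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            km = km_logrank(mrs, meta, oc)
        msio.write_matrix(
            pd.DataFrame({"mrs": mrs.score, "raw_mrs": mrs.raw_score,
                          "risk_group": km.groups}),
            out / f"mrs_{oc}.tsv")
        msio.write_matrix(km.curves.set_index("group"),
                          out / f"km_{oc}.tsv", index_name="group")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            strata = pd.concat(
                [stratified_rerun(mrs, meta, oc, s)
                 for s in ("smoking", "stage")], ignore_index=True)
        msio.write_matrix(strata.set_index("stratum"),
                          out / f"mrs_strata_{oc}.tsv",
                          index_name="stratum")
        summary[oc] = {
            "n_species": len(sel.selected_taxa),
            "hr_per_sd": pooled.hr, "ci95": list(pooled.ci95),
            "p_meta": pooled.p_meta,
            "per_cohort_hr": {c: f.hr for c, f in per_cohort.items()},
            "logrank_chi2": km.logrank_chi2, "logrank_p": km.logrank_p,
            "median_survival_months": km.median_survival,
        }
        print(f"\n[MRS_{tag}] {len(sel.selected_taxa)} species")
        print(f"  pooled HR per SD = {pooled.hr:.2f} "
              f"(95% CI {pooled.ci95[0]:.2f}-{pooled.ci95[1]:.2f}, "
              f"p = {pooled.p_meta:.2e})")
        print(f"  per-cohort HR: "
              + ", ".join(f"{c}: {f.hr:.2f}"
                          for c, f in per_cohort.items()))
        print(f"  log-rank chi2 = {km.logrank_chi2:.1f} "
              f"(p = {km.logrank_p:.2e}); median survival "
              f"low = {km.median_survival['low']:.1f}, "
              f"high = {km.median_survival['high']:.1f} months")
        print(strata.round(3).to_string())
    (out / "mrs_summary.json").write_text(
        json.dumps(summary, indent=2, default=str))


if __name__ == "__main__":
    main()
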