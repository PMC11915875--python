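"""Immune-infiltration and gene-expression links of the risk scores.

Logistic models of median-binarized immune-cell fractions on each MRS
(per-cohort fits pooled by meta-analysis), Spearman correlations of the
selected species' clr abundances with immune fractions and gene
expression, and hypergeometric over-representation of the
microbiome-correlated genes in the supplied gene sets.  The generator
links each causal species to one designated cell type, so those pairs
should surface.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from microsurv import build_mrs
from microsurv import immune as iml
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
    immune_tab = msio.read_matrix(data / "immune_fractions.tsv")
    truth = json.loads((data / "truth.json").read_text())

    selected = set()
    for oc, tag in (("os", "Mortality"), ("rfs", "Relapse")):
        assoc = msio.read_matrix(out / f"associations_{oc}.tsv")
        sel = SelectionResult(assoc["O_j"], assoc["selected"].astype(bool),
                              100, 0.9, 0.05, 0.60, oc)
        if not sel.selected_taxa:
            continue
        selected |= set(sel.selected_taxa)
        mrs = build_mrs(clr, sel, assoc, tag)
        logit = iml.logistic_assoc(immune_tab, mrs, meta)
        msio.write_matrix(logit, out / f"immune_logistic_{oc}.tsv",
                          index_name="cell_type")
        top = logit.dropna().reindex(
            logit["p"].sort_values().index).head(4)
        print(f"\n[MRS_{tag}] strongest immune associations (OR per SD):")
        print(top[["or", "ci_low", "ci_high", "p"]].round(3).to_string())

    corr = iml.spearman_matrix(clr[sorted(selected)], immune_tab)
    msio.write_matrix(corr.set_index("feature"),
                      out / "immune_spearman.tsv", index_name="feature")
    links = {t: c for t, c in truth["immune_links"].items()
             if t in selected}
    found = corr.set_index(["feature", "target"])
    print("\nplanted taxon-cell links among selected species:")
    for taxon, cell in sorted(links.items()):
        row = found.loc[(taxon, cell)]
        print(f"  {taxon} ~ {cell}: r = {row['r']:+.2f} (p = {row['p']:.1e})")

    expr = msio.read_matrix(data / "expression.tsv").T
    gcorr = iml.spearman_matrix(clr[sorted(selected)], expr)
    msio.write_matrix(gcorr.set_index("feature"),
                      out / "gene_spearman.tsv", index_name="feature")
    # a gene counts as microbiome-correlated when its best correlation
    # survives Bonferroni across the selected species tested against it
    n_species = gcorr["feature"].nunique()
    best = gcorr.groupby("target")["p"].min() * n_species
    correlated = sorted(best.index[best < 0.05])
    sets = msio.read_gmt(data / "gene_sets.gmt")
    ora = iml.hypergeom_ora(correlated, list(expr.columns), sets)
    msio.write_matrix(ora, out / "pathway_ora.tsv", index_name="gene_set")
    print(f"\n{len(correlated)} genes correlate with a selected species "
          f"(best pair p, Bonferroni over {n_species} species, < 0.05); "
          "over-representation:")
    print(ora.round(5).to_string())


if __name__ == "__main__":
    main()
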