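#!/usr/bin/env python
"""Differential expression between mutation-status and clinical groups.

For each planted contrast (CYP46A1 mutations, SC5D mutations, the
STRING-CYP46A1 gene set, and pN1 vs pN0 nodal status) runs TMM
normalization, pooled-dispersion estimation and the exact conditional NB
test, then applies the volcano thresholds (|log2FC| >= 2, q < 0.05).
Writes one result table per contrast under results/de/.
"""
import argparse
from pathlib import Path

from oxynet import diffexpr
from oxynet import io as oio
from oxynet import simulate as sim
from oxynet.containers import GeneSet


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results") / "cohort")
    parser.add_argument("--outdir", type=Path, default=Path("results") / "de")
    args = parser.parse_args()
    oio.setup_logging("INFO")
    args.outdir.mkdir(parents=True, exist_ok=True)

    counts = oio.read_expression(args.cohort / "mrna_counts.tsv", layer="mRNA",
                                 scale="counts")
    variants = oio.read_variants(args.cohort / "variants.tsv",
                                 panel=counts.feature_ids)
    clinical = oio.read_clinical(args.cohort / "clinical.tsv").set_index("sample_id")
    factors = diffexpr.tmm_factors(counts)

    string_set = GeneSet("STRING-CYP46A1",
                         ("CYP46A1", "CYP7B1", "CYP27A1", "CYP39A1", "HSD3B7",
                          "CYP7A1", "CYP11A1", "CYP3A4", "CYP3A5", "ABCA1"))
    contrasts = {
        "CYP46A1_mut": dict(variants=variants, genes="CYP46A1"),
        "SC5D_mut": dict(variants=variants, genes="SC5D"),
        "STRING_CYP46A1_mut": dict(variants=variants, genes=string_set),
        "pN1_vs_pN0": dict(clinical=clinical["pN"], positive_level="N1"),
    }
    for label, spec in contrasts.items():
        groups = diffexpr.define_groups(counts.sample_ids, **spec)
        phi = diffexpr.estimate_common_dispersion(counts, groups, factors)
        res = diffexpr.exact_nb_test(counts, groups, phi, factors)
        flagged = diffexpr.volcano_table(res)
        oio.write_results(flagged.sort_values("q"),
                          args.outdir / f"de_{label}.tsv")
        hits = flagged[flagged["significant"]].sort_values("q")
        top = ", ".join(f"{r.gene} (log2FC {r.log2FC:+.2f}, q {r.q:.2g})"
                        for r in hits.head(4).itertuples())
        print(f"{label}: {int((groups == 'group').sum())} vs "
              f"{int((groups == 'reference').sum())} samples, phi={phi:.3f}, "
              f"{len(hits)} genes at q<0.05" + (f": {top}" if top else ""))


if __name__ == "__main__":
    main()
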