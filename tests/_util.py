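"""Shared test helpers: tiny in-memory cohorts and VCF text builders."""

import numpy as np
import pandas as pd

from fhprs.genotype_io import APOE_ALLELES
from fhprs.panel import APOE_RSIDS, ScorePanel
from fhprs.genotype_io import CohortGenotypes

# printed group means used by reproduction checks (score units)
PRINTED_MEANS = {
    ("CONTROL", 12): 33.10, ("FH_M_NEG", 12): 38.25, ("FH_M_POS", 12): 36.48,
    ("CONTROL", 6): 23.03, ("FH_M_NEG", 6): 27.82, ("FH_M_POS", 6): 26.26,
}

# diplotype -> (rs429358, rs7412) unphased genotype strings
DIPLO_GENOTYPES = {
    "E2E2": ("TT", "TT"), "E2E3": ("TT", "CT"), "E2E4": ("CT", "CT"),
    "E3E3": ("TT", "CC"), "E3E4": ("CT", "CC"), "E4E4": ("CC", "CC"),
}


def make_genotypes(panel: ScorePanel, dosages, apoe) -> CohortGenotypes:
    """Build a cohort from per-subject dosage dicts/lists and APOE genotype pairs.

    dosages: list of {rsid: dosage} (missing rsids -> NaN) or list of full rows
    in panel SNP order; apoe: list of (g429358, g7412) strings or None.
    """
    snp_rsids = [v.rsid for v in panel.snp_variants]
    subject_ids = [f"S{i}" for i in range(len(dosages))]
    rows = []
    for d in dosages:
        if isinstance(d, dict):
            rows.append([d.get(r, np.nan) for r in snp_rsids])
        else:
            rows.append(list(d))
    dosage = pd.DataFrame(rows, index=subject_ids, columns=snp_rsids, dtype=float)
    ap = pd.DataFrame(index=subject_ids, columns=list(APOE_RSIDS), dtype=object)
    for sid, pair in zip(subject_ids, apoe):
        g1, g2 = (None, None) if pair is None else pair
        ap.at[sid, "rs429358"] = g1
        ap.at[sid, "rs7412"] = g2
    return CohortGenotypes(subject_ids=subject_ids, dosage=dosage, apoe_genotypes=ap)


def uniform_cohort(panel, dosage_value, diplotype, n=1):
    """n identical subjects with every SNP dosage equal and a given diplotype."""
    snp_rsids = [v.rsid for v in panel.snp_variants]
    return make_genotypes(
        panel,
        [[dosage_value] * len(snp_rsids)] * n,
        [DIPLO_GENOTYPES[diplotype]] * n,
    )


def vcf_text(panel, records, samples):
    """Build a VCF text from (rsid, ref, alt, [gt strings]) tuples."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                   "FORMAT"] + list(samples)),
    ]
    for i, (rsid, ref, alt, gts) in enumerate(records):
        lines.append("\t".join(["1", str(1000 + i * 100), rsid, ref, alt, ".",
                                "PASS", ".", "GT"] + list(gts)))
    return "\n".join(lines) + "\n"
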