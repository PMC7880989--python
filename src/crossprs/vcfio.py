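"""VCF input/output for dosage matrices.

Writing emits a minimal VCFv4.2 with a DS FORMAT field (expected alt
allele count in [0, 2]). Reading uses cyvcf2 and prefers DS, falling back
to the alt-allele count from GT.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alternate allele dosage">
"""


def write_dosage_vcf(dosages: pd.DataFrame, manifest: pd.DataFrame, path) -> None:
    """Write samples x variants dosages as a VCF with DS (and hard-call GT)."""
    samples = list(dosages.index)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in samples)
            + "\n"
        )
        for row in manifest.itertuples(index=False):
            vid = str(row.variant_id)
            ds = dosages[vid].to_numpy(dtype=float)
            gt_codes = np.clip(np.rint(ds), 0, 2).astype(int)
            gts = np.array(["0/0", "0/1", "1/1"])[gt_codes]
            fields = [
                str(row.chrom), str(int(row.pos)), vid, str(row.ref), str(row.alt),
                ".", "PASS", ".", "GT:DS",
            ]
            fields += [f"{g}:{d:g}" for g, d in zip(gts, ds)]
            fh.write("\t".join(fields) + "\n")


def read_dosage_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (dosages, manifest); DS preferred, GT fallback."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    manifest_rows = []
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        try:
            ds = np.asarray(variant.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            ds = None
        if ds is None or len(ds) != len(samples):
            # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
            gt = np.asarray(variant.gt_types)
            ds = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        columns[vid] = ds
        manifest_rows.append(
            {
                "variant_id": vid,
                "chrom": str(variant.CHROM),
                "pos": int(variant.POS),
                "ref": variant.REF,
                "alt": variant.ALT[0] if variant.ALT else ".",
            }
        )
    dosages = pd.DataFrame(columns, index=pd.Index(samples, name="sample_id"))
    return dosages, pd.DataFrame(manifest_rows)
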