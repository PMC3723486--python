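"""Reading and writing the delimited formats the pipeline consumes.

Cohort tables, dosage matrices, risk-allele maps and per-cohort estimate
tables travel as TSV; genotypes may alternatively arrive as VCF (read via
cyvcf2 when installed) or leave as a minimal sites+dosage VCF.  Power and
simulation scenarios come from YAML or JSON config files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, SimulatedCohort
from .grs import GenotypeMatrix, RiskAlleleMap
from .meta import CohortEstimate
from .power import PowerScenario

MISSING_TOKEN = "NA"


def write_cohort_tsv(cohort: SimulatedCohort, path) -> None:
    cohort.data.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN])


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    frame = geno.dosages.copy()
    frame.insert(0, "participant_id", np.arange(1, len(frame) + 1))
    frame.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_dosage_tsv(path, coded_alleles: dict | None = None) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN])
    if "participant_id" in frame.columns:
        frame = frame.drop(columns=["participant_id"])
    return GenotypeMatrix(frame.astype(float), coded_alleles or {})


def read_risk_allele_map(path) -> RiskAlleleMap:
    return RiskAlleleMap.from_frame(pd.read_csv(path, sep="\t"))


def read_estimates_tsv(path) -> list[CohortEstimate]:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for _, r in frame.iterrows():
        out.append(CohortEstimate(
            cohort=str(r["cohort"]), n=int(r["n"]), beta=float(r["beta"]),
            se=float(r["se"]),
            group=str(r["group"]) if "group" in frame.columns and pd.notna(r.get("group")) else None,
        ))
    return out


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def scenario_from_config(config: dict) -> PowerScenario:
    fields = {f.name for f in dataclasses.fields(PowerScenario)}
    unknown = set(config) - fields
    if unknown:
        raise ValueError(f"unknown scenario field(s): {sorted(unknown)}")
    return PowerScenario(**config)


def cohort_spec_from_config(config: dict) -> CohortSpec:
    fields = {f.name for f in dataclasses.fields(CohortSpec)}
    unknown = set(config) - fields
    if unknown:
        raise ValueError(f"unknown cohort field(s): {sorted(unknown)}")
    if "risk_allele_freqs" in config:
        config = dict(config, risk_allele_freqs=tuple(config["risk_allele_freqs"]))
    return CohortSpec(**config)


def write_vcf(geno: GenotypeMatrix, path, amap: RiskAlleleMap | None = None) -> None:
    """Minimal single-sample-per-column VCF with genotypes as GT calls.

    Loci land on synthetic positions (chr1, 1000*i); dosage d of the
    counted allele maps to GT 0/0, 0/1 or 1/1 with the counted allele as
    ALT. Missing dosages become ./. calls.
    """
    n = geno.n_participants
    samples = [f"S{i + 1}" for i in range(n)]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, locus in enumerate(geno.loci):
            alt = geno.coded_alleles.get(locus, "A")
            ref = "G" if alt != "G" else "C"
            if amap is not None and locus in amap:
                entry = amap[locus]
                alt = entry.risk_allele
                ref = entry.other_allele or ref
            calls = [gt_map.get(float(d), "./.") if pd.notna(d) else "./."
                     for d in geno.dosages[locus]]
            fh.write(f"1\t{1000 * (i + 1)}\t{locus}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix counting the ALT allele per site."""
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    loci, columns, alts = [], [], {}
    for variant in vcf:
        rsid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dosage = np.array([
            {0: 0.0, 1: 1.0, 3: 2.0}.get(t, np.nan) for t in variant.gt_types
        ])
        loci.append(rsid)
        columns.append(dosage)
        alts[rsid] = variant.ALT[0] if variant.ALT else "N"
    frame = pd.DataFrame(np.column_stack(columns), columns=loci)
    return GenotypeMatrix(frame, coded_alleles=alts)
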