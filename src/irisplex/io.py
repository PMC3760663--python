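"""Readers and writers for genotypes, phenotypes, parameters and reports.

Genotypes arrive either as a delimited matrix (one column per rs id holding
a dosage or a two-character allele pair) or as a VCF; both are converted to
the same effect-allele dosage representation.  VCF records are matched by
rs id, never by coordinate, so no genome build is assumed.  Phased (``|``)
and unphased (``/``) genotype separators are equivalent: only dosage enters
the model.
"""

from __future__ import annotations

import csv
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    EyeColorCall,
    GenotypeRecord,
    ParameterSet,
    PhenotypeRecord,
    ProbabilityTriple,
)
from .panel import CATEGORIES, SnpPanel, default_panel

logger = logging.getLogger("irisplex")

#: Strings parsed as a missing genotype in delimited input.
MISSING_TOKENS = frozenset({"", ".", "NA", "N/A", "NAN", "./.", ".|."})

PARAMS_FORMAT_TAG = "irisplex-params-v1"


def _parse_cell(value, snp, row_label):
    """One matrix cell -> dosage float (NaN for missing)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return float("nan")
    s = str(value).strip()
    if s.upper() in MISSING_TOKENS:
        return float("nan")
    if s in ("0", "1", "2"):
        return float(s)
    try:
        f = float(s)
    except ValueError:
        f = None
    if f is not None:
        if f in (0.0, 1.0, 2.0):
            return f
        raise ValueError(
            f"row {row_label}, column {snp.rs_id}: dosage must be 0, 1 or 2, got {s!r}"
        )
    pair = s.replace("/", "").replace("|", "").upper()
    try:
        return float(snp.dosage_from_pair(pair))
    except ValueError as exc:
        raise ValueError(f"row {row_label}, column {snp.rs_id}: {exc}") from exc


def read_genotype_csv(path, panel: SnpPanel | None = None) -> list[GenotypeRecord]:
    """Read a genotype matrix (CSV or TSV, sniffed) into dosage records.

    The table needs a ``sample_id`` column (or an unnamed first column) and
    one column per panel rs id; extra columns are ignored with a warning.
    """
    if panel is None:
        panel = default_panel()
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = list(df.columns)
    if "sample_id" in cols:
        id_col = "sample_id"
    else:
        id_col = cols[0]
        logger.warning("no 'sample_id' column; using first column %r as sample id", id_col)
    missing_cols = [rs for rs in panel.rs_ids if rs not in cols]
    if missing_cols:
        raise ValueError(f"genotype table lacks required SNP column(s): {missing_cols}")
    extra = [c for c in cols if c != id_col and c not in panel.rs_ids]
    if extra:
        logger.warning("ignoring non-panel column(s): %s", extra)
    records = []
    for _, row in df.iterrows():
        sid = str(row[id_col])
        dosages = np.array(
            [_parse_cell(row[snp.rs_id], snp, sid) for snp in panel], dtype=float
        )
        records.append(GenotypeRecord(sid, dosages, panel))
    return records


def write_genotype_csv(records: Sequence[GenotypeRecord], path) -> None:
    """Write dosage records as a CSV matrix (integer dosages, '.' for missing)."""
    if not records:
        raise ValueError("no records to write")
    panel = records[0].panel
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", *panel.rs_ids])
        for g in records:
            cells = ["." if math.isnan(d) else str(int(d)) if d == int(d) else repr(d)
                     for d in g.dosages]
            w.writerow([g.sample_id, *cells])


def read_genotype_vcf(path, panel: SnpPanel | None = None) -> list[GenotypeRecord]:
    """Read panel genotypes from a VCF, matching records by rs id.

    Each sample gets one record; panel SNPs absent from the file (or
    no-called) are missing.  Multi-allelic panel records, and records whose
    REF/ALT pair shares no allele with the panel definition (a strand
    mismatch), are hard errors.
    """
    from cyvcf2 import VCF

    if panel is None:
        panel = default_panel()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosage = {sid: np.full(len(panel), np.nan) for sid in samples}
    wanted = set(panel.rs_ids)
    for variant in vcf:
        if variant.ID not in wanted:
            continue
        snp = panel.get(variant.ID)
        j = panel.index_of(variant.ID)
        if len(variant.ALT) != 1:
            raise ValueError(f"{variant.ID}: multi-allelic record not supported for panel SNPs")
        ref, alt = variant.REF.upper(), variant.ALT[0].upper()
        if {ref, alt} != snp.alleles:
            if not ({ref, alt} & snp.alleles):
                raise ValueError(
                    f"{variant.ID}: REF/ALT {ref}/{alt} share no allele with panel "
                    f"{snp.effect_allele}/{snp.other_allele}; resolve strand manually"
                )
            raise ValueError(
                f"{variant.ID}: REF/ALT {ref}/{alt} does not match panel alleles "
                f"{snp.effect_allele}/{snp.other_allele}"
            )
        allele_of = {0: ref, 1: alt}
        for sid, gt in zip(samples, variant.genotypes):
            a = gt[:-1]  # last element is the phased flag
            if len(a) != 2 or any(x < 0 for x in a):
                continue  # no-call stays missing
            dosage[sid][j] = sum(allele_of[x] == snp.effect_allele for x in a)
    vcf.close()
    return [GenotypeRecord(sid, dosage[sid], panel) for sid in samples]


def read_phenotype_csv(path) -> list[PhenotypeRecord]:
    """Read observed eye-colour labels (columns: sample_id + category/eye_color)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cat_col = next((c for c in ("category", "eye_color", "phenotype") if c in df.columns), None)
    if "sample_id" not in df.columns or cat_col is None:
        raise ValueError("phenotype table needs 'sample_id' and 'category'/'eye_color' columns")
    return [
        PhenotypeRecord(str(r["sample_id"]), str(r[cat_col]).strip().lower())
        for _, r in df.iterrows()
    ]


def write_phenotype_csv(records: Sequence[PhenotypeRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "eye_color"])
        for r in records:
            w.writerow([r.sample_id, r.category])


def write_prediction_report(
    records: Sequence[tuple[str, ProbabilityTriple, EyeColorCall]], path
) -> None:
    """Per-sample probabilities and calls, 9 decimal digits (lossless for calls)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "p_blue", "p_intermediate", "p_brown", "call", "threshold"])
        for sid, trip, call in records:
            if not np.all(np.isfinite(trip.as_array())):
                raise ValueError(f"{sid}: non-finite probabilities")
            w.writerow(
                [
                    sid,
                    f"{trip.p_blue:.9f}",
                    f"{trip.p_intermediate:.9f}",
                    f"{trip.p_brown:.9f}",
                    call.call,
                    f"{call.threshold:g}",
                ]
            )


def read_prediction_report(path) -> list[tuple[str, ProbabilityTriple, EyeColorCall]]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    out = []
    for _, r in df.iterrows():
        p = np.array([r["p_blue"], r["p_intermediate"], r["p_brown"]], dtype=float)
        p = p / p.sum()  # remove 1e-9-scale rounding from the fixed-precision file
        trip = ProbabilityTriple(*p)
        out.append(
            (
                str(r["sample_id"]),
                trip,
                EyeColorCall(str(r["call"]), float(r["threshold"]), float(p.max())),
            )
        )
    return out


def write_genotype_vcf(records: Sequence[GenotypeRecord], path) -> None:
    """Write integer-dosage records as a minimal single-chromosome VCF.

    REF is the other allele, ALT the effect allele, so GT allele counts
    equal the stored dosage.  Positions are synthetic (records are matched
    back by rs id, never by coordinate).  Imputed (fractional) dosages
    cannot be represented and are rejected.
    """
    if not records:
        raise ValueError("no records to write")
    panel = records[0].panel
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_id for g in records)
            + "\n"
        )
        for j, snp in enumerate(panel):
            gts = []
            for g in records:
                d = g.dosages[j]
                if math.isnan(d):
                    gts.append("./.")
                elif d in gt_of:
                    gts.append(gt_of[d])
                else:
                    raise ValueError(
                        f"{g.sample_id}: fractional dosage {d} at {snp.rs_id} "
                        "cannot be written as a VCF genotype"
                    )
            fh.write(
                f"1\t{j + 1}\t{snp.rs_id}\t{snp.other_allele}\t{snp.effect_allele}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Parameter files (versioned YAML schema)


def load_parameters(path=None, panel: SnpPanel | None = None) -> ParameterSet:
    """Load a parameter file; ``path=None`` loads the shipped, externally
    sourced published coefficients."""
    if path is None:
        from importlib import resources

        text = resources.files("irisplex.data").joinpath("published_params.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if doc.get("format") != PARAMS_FORMAT_TAG:
        raise ValueError(f"unrecognised parameter format tag: {doc.get('format')!r}")
    if panel is None:
        panel = default_panel()
    order = list(doc["panel"])
    if set(order) != set(panel.rs_ids):
        raise ValueError(
            f"parameter file panel {order} does not match panel {list(panel.rs_ids)}"
        )
    ref = doc["reference_category"]
    alpha = {k: float(v) for k, v in doc["alpha"].items()}
    beta = {
        k: np.array([float(doc["beta"][k][rs]) for rs in panel.rs_ids])
        for k in doc["beta"]
    }
    return ParameterSet(
        reference_category=ref,
        alpha=alpha,
        beta=beta,
        panel=panel,
        provenance=str(doc.get("provenance", "")),
    )


def save_parameters(params: ParameterSet, path) -> None:
    doc = {
        "format": PARAMS_FORMAT_TAG,
        "provenance": params.provenance,
        "reference_category": params.reference_category,
        "panel": list(params.panel.rs_ids),
        "alpha": {k: float(v) for k, v in params.alpha.items()},
        "beta": {
            k: {rs: float(b) for rs, b in zip(params.panel.rs_ids, params.beta[k])}
            for k in params.beta
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
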