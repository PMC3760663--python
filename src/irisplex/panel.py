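"""SNP panel definitions: which markers are modelled and which allele is counted.

The prediction model works on *effect-allele dosages*: for each marker the
number of copies (0, 1 or 2) of a designated allele in the diploid genotype.
Which allele is counted is part of the model definition, so it is stored on
each :class:`SnpDef` and shipped in a data file rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import yaml

VALID_BASES = frozenset("ACGT")

#: Canonical eye-colour categories, in fixed I/O order.
CATEGORIES = ("blue", "intermediate", "brown")


@dataclass(frozen=True)
class SnpDef:
    """A single bi-allelic SNP with a declared effect-allele orientation."""

    rs_id: str
    gene: str
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES:
            raise ValueError(f"{self.rs_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_BASES:
            raise ValueError(f"{self.rs_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rs_id}: effect and other allele must differ")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))

    def dosage_from_pair(self, pair: str) -> int:
        """Effect-allele count in an unordered two-character genotype ("CT" == "TC")."""
        pair = pair.strip().upper()
        if len(pair) != 2 or any(a not in VALID_BASES for a in pair):
            raise ValueError(f"{self.rs_id}: invalid genotype string {pair!r}")
        if any(a not in self.alleles for a in pair):
            raise ValueError(
                f"{self.rs_id}: genotype {pair!r} contains alleles outside "
                f"{{{self.effect_allele},{self.other_allele}}}"
            )
        return sum(1 for a in pair if a == self.effect_allele)


@dataclass(frozen=True)
class SnpPanel:
    """An ordered collection of SNPs; the order fixes the coefficient order."""

    snps: tuple[SnpDef, ...]

    def __post_init__(self) -> None:
        ids = [s.rs_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate rs_id in panel")
        object.__setattr__(self, "snps", tuple(self.snps))

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[SnpDef]:
        return iter(self.snps)

    @property
    def rs_ids(self) -> tuple[str, ...]:
        return tuple(s.rs_id for s in self.snps)

    def index_of(self, rs_id: str) -> int:
        return self.rs_ids.index(rs_id)

    def get(self, rs_id: str) -> SnpDef:
        for s in self.snps:
            if s.rs_id == rs_id:
                return s
        raise KeyError(rs_id)


def load_panel(path=None) -> SnpPanel:
    """Load a panel from a YAML file; defaults to the shipped IrisPlex panel."""
    if path is None:
        text = resources.files("irisplex.data").joinpath("irisplex_panel.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if doc.get("format") != "irisplex-panel-v1":
        raise ValueError(f"unrecognised panel format tag: {doc.get('format')!r}")
    snps = tuple(
        SnpDef(
            rs_id=entry["rs_id"],
            gene=entry.get("gene", ""),
            effect_allele=entry["effect_allele"],
            other_allele=entry["other_allele"],
        )
        for entry in doc["snps"]
    )
    return SnpPanel(snps)


def default_panel() -> SnpPanel:
    """The six-SNP IrisPlex panel (HERC2, OCA2, SLC45A2, TYR, SLC24A4, IRF4)."""
    return load_panel(None)
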