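"""Factorial study design for genotype x treatment qPCR/trait experiments.

The default design mirrors a two-genotype wheat heat-stress field study:
a heat-tolerant cultivar (Misr2) and a heat-susceptible line (Line4) grown
under a normal sowing date ("control") and a late sowing date ("stress"),
with three biological replicates per cell and three technical qPCR
replicates per biological replicate. Eight heat-responsive target genes
(heat-shock proteins, antioxidant enzymes, peroxisome-biogenesis factors)
are quantified against the Actin-7 reference gene, alongside twelve
phenotypic traits.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "Genotype",
    "Trait",
    "StudyDesign",
    "build_design",
    "PAPER_GENES",
    "PAPER_TRAITS",
    "PCA_DEFAULT_TRAITS",
    "REFERENCE_GENE",
    "TREATMENTS",
]

#: Target genes in canonical order.
PAPER_GENES: tuple[str, ...] = (
    "TaHSP70",
    "TaHSP90",
    "TaSOD",
    "TaCAT1",
    "TaPEX11.3",
    "TaPEX11.4",
    "TaFIS1A",
    "TaDRP5B",
)

REFERENCE_GENE = "Actin-7"

TREATMENTS: tuple[str, str] = ("control", "stress")


@dataclass(frozen=True)
class Genotype:
    """A genotype label with its heat-tolerance class."""

    label: str
    tolerance: str  # "tolerant" | "susceptible"

    def __post_init__(self) -> None:
        if self.tolerance not in ("tolerant", "susceptible"):
            raise ValueError(
                f"tolerance must be 'tolerant' or 'susceptible', got {self.tolerance!r}"
            )


@dataclass(frozen=True)
class Trait:
    """A phenotypic trait label with its measurement unit."""

    label: str
    unit: str


#: Measured phenotypic traits (unit metadata travels with the trait table).
PAPER_TRAITS: tuple[Trait, ...] = (
    Trait("grain_yield", "g/m2"),
    Trait("h2o2", "umol/g FW"),
    Trait("tss", "mg/g DW"),
    Trait("proline", "umol/g FW"),
    Trait("mda", "nmol/g FW"),
    Trait("chl_a", "mg/g FW"),
    Trait("chl_b", "mg/g FW"),
    Trait("carotenoids", "mg/g FW"),
    Trait("sod_activity", "U/mg protein"),
    Trait("pox_activity", "U/mg protein"),
    Trait("cat_activity", "U/mg protein"),
    Trait("peroxisome_abundance", "RFU"),
)

#: The ten traits entering the default trait-gene PCA (proline and peroxisome
#: abundance are measured but not part of the default multivariate list).
PCA_DEFAULT_TRAITS: tuple[str, ...] = (
    "chl_a",
    "chl_b",
    "carotenoids",
    "tss",
    "h2o2",
    "mda",
    "sod_activity",
    "pox_activity",
    "cat_activity",
    "grain_yield",
)


@dataclass(frozen=True)
class StudyDesign:
    """Complete factorial layout of a two-treatment expression/trait study.

    Invariants enforced at construction: exactly two treatments, unique
    labels everywhere, at least two biological replicates, at least one
    technical replicate, and a reference gene distinct from the targets.
    """

    genotypes: tuple[Genotype, ...] = (
        Genotype("Misr2", "tolerant"),
        Genotype("Line4", "susceptible"),
    )
    treatments: tuple[str, str] = TREATMENTS
    n_bio: int = 3
    n_tech: int = 3
    genes: tuple[str, ...] = PAPER_GENES
    reference_gene: str = REFERENCE_GENE
    traits: tuple[Trait, ...] = PAPER_TRAITS

    def __post_init__(self) -> None:
        if len(self.treatments) != 2:
            raise ValueError("a design has exactly two treatments (control, stress)")
        if len(set(self.treatments)) != 2:
            raise ValueError("treatment labels must be distinct")
        labels = [g.label for g in self.genotypes]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate genotype labels: {labels}")
        if self.n_bio < 2:
            raise ValueError("at least two biological replicates are required")
        if self.n_tech < 1:
            raise ValueError("at least one technical replicate is required")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene labels")
        if self.reference_gene in self.genes:
            raise ValueError("the reference gene cannot also be a target gene")
        trait_labels = [t.label for t in self.traits]
        if len(set(trait_labels)) != len(trait_labels):
            raise ValueError("duplicate trait labels")

    @property
    def genotype_labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.genotypes)

    @property
    def tolerant(self) -> str:
        """Label of the (first) tolerant genotype."""
        for g in self.genotypes:
            if g.tolerance == "tolerant":
                return g.label
        raise ValueError("design has no tolerant genotype")

    @property
    def susceptible(self) -> str:
        for g in self.genotypes:
            if g.tolerance == "susceptible":
                return g.label
        raise ValueError("design has no susceptible genotype")

    @property
    def trait_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.traits)

    @property
    def trait_units(self) -> dict[str, str]:
        return {t.label: t.unit for t in self.traits}

    @property
    def n_cells(self) -> int:
        return len(self.genotypes) * 2


def build_design(config: Mapping | None = None) -> StudyDesign:
    """Build a :class:`StudyDesign` from a configuration mapping.

    ``config=None`` (or an empty mapping) returns the default two-genotype
    wheat design: 2 genotypes x 2 treatments x 3 biological x 3 technical
    replicates, 8 target genes plus Actin-7, 12 traits.

    Recognised keys: ``genotypes`` (list of ``{label, tolerance}``),
    ``treatments``, ``n_bio``, ``n_tech``, ``genes``, ``reference_gene``,
    ``traits`` (list of ``{label, unit}``).
    """
    if not config:
        return StudyDesign()
    kwargs: dict = {}
    if "genotypes" in config:
        kwargs["genotypes"] = tuple(
            g if isinstance(g, Genotype) else Genotype(g["label"], g["tolerance"])
            for g in config["genotypes"]
        )
    if "treatments" in config:
        kwargs["treatments"] = tuple(config["treatments"])
    for key in ("n_bio", "n_tech", "reference_gene"):
        if key in config:
            kwargs[key] = config[key]
    if "genes" in config:
        kwargs["genes"] = tuple(config["genes"])
    if "traits" in config:
        kwargs["traits"] = tuple(
            t if isinstance(t, Trait) else Trait(t["label"], t["unit"])
            for t in config["traits"]
        )
    return StudyDesign(**kwargs)
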