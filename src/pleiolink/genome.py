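"""Genetic architectures: linkage groups, locus roles, and map distances.

A genome here is a set of chromosomes carrying causal loci (continuum-of-alleles
QTL or biallelic QTN) affecting one or both of two quantitative traits, plus
optional panels of diallelic neutral markers used for association mapping.

Two architecture kinds are contrasted throughout the package:

``pleiotropy``
    every causal locus affects both traits (one mutation moves both traits);
``linkage``
    causal loci come in physically linked pairs, one member per trait, so
    cross-trait covariance can only arise through linkage disequilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Role",
    "LocusDescriptor",
    "NeutralPanelSpec",
    "ArchitectureSpec",
    "build_architecture",
    "recombination_fraction",
]


class Role:
    """String constants for locus roles."""

    QTL_TRAIT1 = "qtl_trait1"
    QTL_TRAIT2 = "qtl_trait2"
    QTL_PLEIO = "qtl_pleio"
    QTN_TRAIT1 = "qtn_trait1"
    QTN_TRAIT2 = "qtn_trait2"
    QTN_PLEIO = "qtn_pleio"
    NEUTRAL = "neutral"

    CAUSAL = (QTL_TRAIT1, QTL_TRAIT2, QTL_PLEIO, QTN_TRAIT1, QTN_TRAIT2, QTN_PLEIO)
    QTN = (QTN_TRAIT1, QTN_TRAIT2, QTN_PLEIO)
    PLEIO = (QTL_PLEIO, QTN_PLEIO)


_ROLE_TRAITS = {
    Role.QTL_TRAIT1: frozenset({1}),
    Role.QTL_TRAIT2: frozenset({2}),
    Role.QTL_PLEIO: frozenset({1, 2}),
    Role.QTN_TRAIT1: frozenset({1}),
    Role.QTN_TRAIT2: frozenset({2}),
    Role.QTN_PLEIO: frozenset({1, 2}),
    Role.NEUTRAL: frozenset(),
}


def recombination_fraction(d_cM):
    """Haldane map function: recombination fraction for a map distance in cM.

    r = (1 - exp(-2 d / 100)) / 2, assuming no crossover interference.
    r = 0 at d = 0 and r -> 1/2 for unlinked loci; for small distances
    r ~= d/100 (1 cM ~= 1% recombination).
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cM) else r


@dataclass(frozen=True)
class LocusDescriptor:
    """One locus: global index, chromosome, map position, and role."""

    id: int
    chromosome: int
    position_cM: float
    role: str

    def __post_init__(self):
        if self.role not in _ROLE_TRAITS:
            raise ValueError(f"unknown locus role {self.role!r}")
        if self.position_cM < 0:
            raise ValueError("position_cM must be nonnegative")

    @property
    def traits_affected(self) -> frozenset:
        return _ROLE_TRAITS[self.role]


@dataclass(frozen=True)
class NeutralPanelSpec:
    """Panel of diallelic neutral markers flanking each causal position.

    Defaults describe a dense panel: ``n_neutral_per_chromosome`` equidistant
    markers on a ``chromosome_length_cM`` map with the causal locus (or fully
    linked pair) at the center, giving a recombination fraction of ~1e-6
    between adjacent markers at the default spacing of 1e-4 cM.
    """

    n_neutral_per_chromosome: int = 1000
    chromosome_length_cM: float = 0.1
    neutral_mu: float = 1e-6

    @property
    def adjacent_spacing_cM(self) -> float:
        return self.chromosome_length_cM / (self.n_neutral_per_chromosome - 1)

    @property
    def adjacent_recomb(self) -> float:
        return recombination_fraction(self.adjacent_spacing_cM)


@dataclass
class ArchitectureSpec:
    """A complete genome layout with derived arrays used by the simulator.

    ``loci`` is ordered by (chromosome, position); this genome order defines
    the columns of every genotype matrix downstream.
    """

    loci: list
    n_chromosomes: int
    chromosome_lengths_cM: list
    architecture_kind: str
    within_pair_cM: float = 0.0
    between_pair_cM: float | None = None
    neutral_panel: NeutralPanelSpec | None = None

    # derived, filled in __post_init__
    chrom: np.ndarray = field(init=False, repr=False)
    pos: np.ndarray = field(init=False, repr=False)
    roles: np.ndarray = field(init=False, repr=False)
    causal_idx: np.ndarray = field(init=False, repr=False)
    neutral_idx: np.ndarray = field(init=False, repr=False)
    trait_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.chrom = np.array([l.chromosome for l in self.loci], dtype=np.int32)
        self.pos = np.array([l.position_cM for l in self.loci], dtype=float)
        self.roles = np.array([l.role for l in self.loci], dtype=object)
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(self.loci))):
            raise ValueError("loci must be listed in genome order")
        self.causal_idx = np.flatnonzero(self.roles != Role.NEUTRAL)
        self.neutral_idx = np.flatnonzero(self.roles == Role.NEUTRAL)
        # trait_matrix[c, k] = 1 if causal locus c affects trait k+1
        tm = np.zeros((len(self.causal_idx), 2))
        for row, li in enumerate(self.causal_idx):
            for t in self.loci[li].traits_affected:
                tm[row, t - 1] = 1.0
        self.trait_matrix = tm

    # -- sizes ------------------------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_causal(self) -> int:
        return len(self.causal_idx)

    @property
    def n_neutral(self) -> int:
        return len(self.neutral_idx)

    def n_loci_per_trait(self, trait: int) -> int:
        return int(self.trait_matrix[:, trait - 1].sum())

    @property
    def is_qtn(self) -> bool:
        return any(r in Role.QTN for r in self.roles[self.causal_idx])

    # -- recombination ----------------------------------------------------
    def interval_recomb(self) -> np.ndarray:
        """Recombination fraction between adjacent loci in genome order.

        Length ``n_loci - 1``; intervals spanning a chromosome boundary get
        r = 1/2 (independent assortment).
        """
        d = np.diff(self.pos)
        r = recombination_fraction(np.maximum(d, 0.0))
        r[np.diff(self.chrom) != 0] = 0.5
        return r

    # -- serialization ----------------------------------------------------
    def to_config(self) -> str:
        """Serialize to a YAML document (round-trips via from_config)."""
        doc = {
            "architecture_kind": self.architecture_kind,
            "n_chromosomes": self.n_chromosomes,
            "chromosome_lengths_cM": [float(x) for x in self.chromosome_lengths_cM],
            "within_pair_cM": float(self.within_pair_cM),
            "between_pair_cM": None
            if self.between_pair_cM is None
            else float(self.between_pair_cM),
            "neutral_panel": None
            if self.neutral_panel is None
            else {
                "n_neutral_per_chromosome": self.neutral_panel.n_neutral_per_chromosome,
                "chromosome_length_cM": self.neutral_panel.chromosome_length_cM,
                "neutral_mu": self.neutral_panel.neutral_mu,
            },
            "loci": [
                [int(l.id), int(l.chromosome), float(l.position_cM), l.role]
                for l in self.loci
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_config(cls, text: str) -> "ArchitectureSpec":
        doc = yaml.safe_load(text)
        panel = doc.get("neutral_panel")
        return cls(
            loci=[LocusDescriptor(i, c, p, r) for i, c, p, r in doc["loci"]],
            n_chromosomes=doc["n_chromosomes"],
            chromosome_lengths_cM=doc["chromosome_lengths_cM"],
            architecture_kind=doc["architecture_kind"],
            within_pair_cM=doc.get("within_pair_cM", 0.0),
            between_pair_cM=doc.get("between_pair_cM"),
            neutral_panel=None if panel is None else NeutralPanelSpec(**panel),
        )

    def to_bim_rows(self):
        """PLINK .bim-compatible rows (chrom, id, cM, bp, A1, A2).

        Dummy base-pair coordinate = round(cM * 1e4) so distinct map
        positions stay distinct.
        """
        rows = []
        for l in self.loci:
            rows.append(
                (
                    l.chromosome + 1,
                    f"L{l.id}",
                    l.position_cM,
                    int(round(l.position_cM * 1e4)) + 1,
                    "A",
                    "T",
                )
            )
        return rows


def _causal_roles(kind: str, biallelic: bool):
    if kind == "pleiotropy":
        return (Role.QTN_PLEIO,) if biallelic else (Role.QTL_PLEIO,)
    if biallelic:
        return (Role.QTN_TRAIT1, Role.QTN_TRAIT2)
    return (Role.QTL_TRAIT1, Role.QTL_TRAIT2)


def build_architecture(
    kind: str,
    n_loci_per_trait: int,
    within_pair_cM: float = 0.0,
    between_pair_cM: float | None = None,
    neutral_panel: NeutralPanelSpec | None = None,
    biallelic: bool = False,
) -> ArchitectureSpec:
    """Build one of the standard genome layouts.

    Parameters
    ----------
    kind
        ``"pleiotropy"`` (one locus affecting both traits per unit) or
        ``"linkage"`` (a pair of single-trait loci ``within_pair_cM`` apart,
        trait-1 member first).
    n_loci_per_trait
        Number of causal loci affecting each trait (default setups use 120;
        a 60-locus variant is supported).
    between_pair_cM
        If given, all pairs (or pleiotropic loci) are placed on a *single*
        chromosome at this spacing; otherwise each unit gets its own
        chromosome and assorts independently of the others.
    neutral_panel
        If given, each unit's chromosome additionally carries the panel's
        equidistant diallelic markers with the causal unit at the center
        (requires one unit per chromosome, i.e. ``between_pair_cM is None``).
    biallelic
        Use biallelic QTN roles instead of continuum-of-alleles QTL.
    """
    if kind not in ("pleiotropy", "linkage"):
        raise ValueError(f"unknown architecture kind {kind!r}")
    if n_loci_per_trait < 1:
        raise ValueError("n_loci_per_trait must be >= 1")
    if within_pair_cM < 0 or (between_pair_cM is not None and between_pair_cM < 0):
        raise ValueError("map distances must be nonnegative")
    if kind == "pleiotropy" and within_pair_cM > 0:
        raise ValueError("pleiotropy kind has no within-pair distance")
    if neutral_panel is not None and between_pair_cM is not None:
        raise ValueError("neutral panel requires one causal unit per chromosome")

    roles = _causal_roles(kind, biallelic)
    n_units = n_loci_per_trait

    loci: list[LocusDescriptor] = []
    chrom_lengths: list[float] = []
    next_id = 0

    def add(chromosome, position, role):
        nonlocal next_id
        loci.append(LocusDescriptor(next_id, chromosome, position, role))
        next_id += 1

    if between_pair_cM is not None:
        # all units on a single chromosome, unit i anchored at i * spacing
        n_chrom = 1
        for i in range(n_units):
            anchor = i * between_pair_cM
            if kind == "pleiotropy":
                add(0, anchor, roles[0])
            else:
                add(0, anchor, roles[0])
                add(0, anchor + within_pair_cM, roles[1])
        span = (n_units - 1) * between_pair_cM + (
            within_pair_cM if kind == "linkage" else 0.0
        )
        chrom_lengths = [span]
    else:
        n_chrom = n_units
        for c in range(n_units):
            if neutral_panel is None:
                if kind == "pleiotropy":
                    add(c, 0.0, roles[0])
                    chrom_lengths.append(0.0)
                else:
                    add(c, 0.0, roles[0])
                    add(c, within_pair_cM, roles[1])
                    chrom_lengths.append(within_pair_cM)
            else:
                L = neutral_panel.chromosome_length_cM
                n_snp = neutral_panel.n_neutral_per_chromosome
                center = L / 2.0
                if kind == "pleiotropy":
                    causal = [(center, roles[0])]
                else:
                    causal = [
                        (center - within_pair_cM / 2.0, roles[0]),
                        (center + within_pair_cM / 2.0, roles[1]),
                    ]
                snp_pos = np.linspace(0.0, L, n_snp)
                merged = sorted(
                    [(p, Role.NEUTRAL) for p in snp_pos] + causal,
                    key=lambda t: (t[0], t[1] != Role.NEUTRAL),
                )
                for p, role in merged:
                    add(c, p, role)
                chrom_lengths.append(L)

    return ArchitectureSpec(
        loci=loci,
        n_chromosomes=n_chrom,
        chromosome_lengths_cM=chrom_lengths,
        architecture_kind=kind,
        within_pair_cM=within_pair_cM,
        between_pair_cM=between_pair_cM,
        neutral_panel=neutral_panel,
    )
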