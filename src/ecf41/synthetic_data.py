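"""Synthetic genomes with ECF41-like loci, planted promoters, and truth.

The generator emulates the statistical structure the downstream analysis
assumes: replicons of configurable base composition carrying ECF41 loci
drawn from the five conserved neighborhood categories (plus ``ungrouped``)
at configurable proportions, bipartite promoter sites sampled column-wise
from a generator motif model (-35 near TGTCACA, spacer in {15,16,17}, -10
near CGTC) placed inside 250 bp upstream windows, decoy half-sites, and
non-ECF background genes.  Every stochastic choice flows through one RNG
stream seeded from the configuration, so a fixed seed reproduces the
output byte for byte.  Ground truth (locus categories, site coordinates,
the generator model itself) is returned and written alongside the data.

Geometry choices (gene lengths uniform on 300-1500 bp, operon gaps of
20-80 bp, inter-locus gaps of 300-600 bp, a 160-300 bp shared region for
divergent pairs) keep upstream windows of distinct genes disjoint on a
given strand, so hit-to-gene assignment on noiseless data is exact.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ecf41 import io as ecf_io
from ecf41.locus_context import GeneRecord
from ecf41.promoter_model import BipartiteMotifModel, reverse_complement
from ecf41.protein_features import ArchitectureAnnotation

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
LINKER_MOTIF = "WLPEP"

#: Default neighborhood-category proportions (fractions of 373 loci).
DEFAULT_CATEGORY_PROPORTIONS = {
    "ECF_alone": 0.34,
    "COE_up_same": 0.29,
    "COE_down_same": 0.14,
    "convergent": 0.02,
    "divergent": 0.15,
    "ungrouped": 0.06,
}

#: Default probability that a gene of a given role in a given category
#: carries the promoter motif (ratios of the observed occurrence counts).
DEFAULT_PROMOTER_OCCURRENCE = {
    ("ECF_alone", "ECF"): 38 / 126,
    ("COE_up_same", "ECF"): 0.0,
    ("COE_up_same", "COE"): 97 / 107,
    ("COE_down_same", "ECF"): 14 / 53,
    ("COE_down_same", "COE"): 24 / 53,
    ("convergent", "ECF"): 3 / 9,
    ("convergent", "COE"): 4 / 9,
    ("divergent", "ECF"): 36 / 55,
    ("divergent", "COE"): 41 / 55,
    ("ungrouped", "ECF"): 0.0,
}

#: Spacer distribution: 16 +/- 1 bp with 16 modal.
DEFAULT_SPACER_PROBS = {15: 0.2, 16: 0.6, 17: 0.2}

#: Phylum proportions of ECF41 proteins (fractions of 373).
DEFAULT_PHYLUM_PROPORTIONS = {
    "Actinobacteria": 252 / 373,
    "Proteobacteria": 84 / 373,
    "Firmicutes": 15 / 373,
    "Chloroflexi": 11 / 373,
    "Acidobacteria": 4 / 373,
    "Bacteriodetes": 2 / 373,
    "Cyanobacteria": 2 / 373,
    "Spirochaetes": 1 / 373,
    "Verrucomicrobia": 1 / 373,
    "Gemmatimonadetes": 1 / 373,
}

_COE_PRODUCTS = {
    "carboxymuconolactone_decarboxylase": "putative carboxymuconolactone decarboxylase",
    "oxidoreductase": "NAD(P)H-dependent oxidoreductase",
    "epimerase": "NAD-dependent epimerase",
}
_COE_DOMAIN_CHOICES = {
    "carboxymuconolactone_decarboxylase": ["PF02627"],
    "oxidoreductase": [
        "Oxidored_FMN", "Flavodoxin_2", "Pyr_redox", "Pyr_redox_2",
        "FAD_binding_2", "FAD_binding_3", "FAD_binding_4",
        "Amino_oxidase", "Pyridox_oxidase", "FMN_red",
    ],
    "epimerase": ["NmrA", "Epimerase"],
}
_BACKGROUND_PRODUCTS = [
    "putative membrane protein",
    "ABC transporter ATP-binding protein",
    "MFS family permease",
    "ribosomal protein",
    "two-component response regulator",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-genome generator (defaults = the study
    conditions the analysis is meant to reproduce)."""

    seed: int = 42
    n_replicons: int = 2
    replicon_length: int = 100_000
    gc_content: float = 0.45
    n_ecf_loci: int = 40
    category_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    promoter_occurrence: dict = field(
        default_factory=lambda: dict(DEFAULT_PROMOTER_OCCURRENCE)
    )
    spacer_probs: dict = field(default_factory=lambda: dict(DEFAULT_SPACER_PROBS))
    upstream_window: int = 250
    planted_minus35: str = "TGTCACA"
    planted_minus10: str = "CGTC"
    site_mutation_rate: float = 0.0
    decoy_rate: float = 0.2  # isolated half-sites per kb
    phylum_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_PROPORTIONS)
    )
    # gene geometry
    gene_length_range: tuple = (300, 1500)
    operon_gap_range: tuple = (20, 80)
    locus_gap_range: tuple = (300, 600)
    divergent_gap_range: tuple = (160, 300)
    # protein model
    protein_sigma2_end: int = 80
    protein_sigma4_end: int = 170
    protein_length: int = 270
    within_phylum_divergence: float = 0.1

    def __post_init__(self) -> None:
        for name, dist in (
            ("category_proportions", self.category_proportions),
            ("spacer_probs", self.spacer_probs),
            ("phylum_proportions", self.phylum_proportions),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(v < 0 for v in dist.values()):
                raise ValueError(f"{name} has negative entries")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.site_mutation_rate <= 1.0:
            raise ValueError("site_mutation_rate must be in [0, 1]")

    @property
    def background(self) -> np.ndarray:
        """Base probabilities in ACGT order implied by the GC content."""
        at, gc = (1.0 - self.gc_content) / 2.0, self.gc_content / 2.0
        return np.array([at, gc, gc, at])

    def to_json(self, path) -> None:
        data = dataclasses.asdict(self)
        data["promoter_occurrence"] = {
            f"{cat}:{role}": p for (cat, role), p in self.promoter_occurrence.items()
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, default=list)
            fh.write("\n")


@dataclass
class LocusTruth:
    ecf_gene_id: str
    category: str
    partner_gene_id: Optional[str]
    coe_class: str
    phylum: str
    species: str
    promoter_on_ecf: bool
    promoter_on_coe: Optional[bool]


@dataclass
class SiteTruth:
    replicon_id: str
    strand: str
    start: int
    end: int
    minus35_start: int
    spacer: int
    target_gene_id: str


@dataclass
class SyntheticTruth:
    loci: list
    sites: list
    generator_model: BipartiteMotifModel


@dataclass
class SyntheticDataset:
    """Everything `simulate` produces, with writers for the on-disk form."""

    config: SimulationConfig
    replicons: dict
    genes: list
    domains: dict
    proteins: dict
    architectures: dict
    truth: SyntheticTruth

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        p = lambda name: os.path.join(outdir, name)
        ecf_io.write_fasta(self.replicons, p("genome.fasta"))
        lengths = {rid: len(seq) for rid, seq in self.replicons.items()}
        ecf_io.write_gff3(self.genes, p("annotation.gff3"), lengths)
        ecf_io.write_domain_table(self.domains, p("domains.tsv"))
        ecf_io.write_fasta(self.proteins, p("proteins.fasta"))
        self.truth.generator_model.to_json(p("generator_model.json"))
        self.config.to_json(p("config.json"))
        with open(p("truth_loci.tsv"), "w") as fh:
            fh.write(
                "ecf_gene_id\tcategory\tpartner_gene_id\tcoe_class\tphylum\t"
                "species\tpromoter_on_ecf\tpromoter_on_coe\n"
            )
            for lt in self.truth.loci:
                coe_flag = "" if lt.promoter_on_coe is None else int(lt.promoter_on_coe)
                fh.write(
                    f"{lt.ecf_gene_id}\t{lt.category}\t{lt.partner_gene_id or ''}\t"
                    f"{lt.coe_class}\t{lt.phylum}\t{lt.species}\t"
                    f"{int(lt.promoter_on_ecf)}\t{coe_flag}\n"
                )
        with open(p("truth_sites.tsv"), "w") as fh:
            fh.write(
                "replicon_id\tstrand\tstart\tend\tminus35_start\tspacer\ttarget_gene_id\n"
            )
            for st in self.truth.sites:
                fh.write(
                    f"{st.replicon_id}\t{st.strand}\t{st.start}\t{st.end}\t"
                    f"{st.minus35_start}\t{st.spacer}\t{st.target_gene_id}\n"
                )


def read_truth(outdir) -> SyntheticTruth:
    """Read truth files back (round-trips what :meth:`SyntheticDataset.write`
    emits)."""
    loci, sites = [], []
    with open(os.path.join(outdir, "truth_loci.tsv")) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            loci.append(
                LocusTruth(
                    ecf_gene_id=f[0], category=f[1],
                    partner_gene_id=f[2] or None, coe_class=f[3],
                    phylum=f[4], species=f[5],
                    promoter_on_ecf=bool(int(f[6])),
                    promoter_on_coe=None if f[7] == "" else bool(int(f[7])),
                )
            )
    with open(os.path.join(outdir, "truth_sites.tsv")) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(
                SiteTruth(
                    replicon_id=f[0], strand=f[1], start=int(f[2]), end=int(f[3]),
                    minus35_start=int(f[4]), spacer=int(f[5]), target_gene_id=f[6],
                )
            )
    model = BipartiteMotifModel.from_json(os.path.join(outdir, "generator_model.json"))
    return SyntheticTruth(loci=loci, sites=sites, generator_model=model)


def generator_motif_model(
    minus35: str = "TGTCACA",
    minus10: str = "CGTC",
    spacer_probs: Optional[dict] = None,
    mutation_rate: float = 0.0,
    background: Optional[np.ndarray] = None,
) -> BipartiteMotifModel:
    """PWMs of the planting process: each position keeps its consensus base
    with probability ``1 - mu`` and is otherwise substituted uniformly over
    all four bases, so p(consensus) = 1 - 3mu/4 and p(other) = mu/4."""
    from ecf41.promoter_model import _BASE_INDEX, UNIFORM_BACKGROUND

    def pwm(consensus_text: str) -> np.ndarray:
        out = np.full((len(consensus_text), 4), mutation_rate / 4.0)
        for j, c in enumerate(consensus_text.upper()):
            out[j, _BASE_INDEX[c]] += 1.0 - mutation_rate
        return out

    return BipartiteMotifModel(
        pwm35=pwm(minus35),
        pwm10=pwm(minus10),
        spacer_probs=dict(spacer_probs or DEFAULT_SPACER_PROBS),
        background=(
            UNIFORM_BACKGROUND.copy() if background is None
            else np.asarray(background, float)
        ),
    )


def _sample_site(
    model: BipartiteMotifModel, rng: np.random.Generator
) -> tuple[str, int]:
    """Sample (site text, spacer): blocks column-wise from the generator
    PWMs, spacer from the spacer distribution, spacer bases from the
    background."""
    bases = np.array(list("ACGT"))
    spacers = model.spacers
    spacer = int(rng.choice(spacers, p=[model.spacer_probs[s] for s in spacers]))
    text35 = "".join(rng.choice(bases, p=col) for col in model.pwm35)
    text10 = "".join(rng.choice(bases, p=col) for col in model.pwm10)
    filler = "".join(rng.choice(bases, size=spacer, p=model.background))
    return text35 + filler + text10, spacer


def plant_site(
    window: str, model: BipartiteMotifModel, rng: np.random.Generator
) -> tuple[str, dict]:
    """Plant one sampled bipartite site at a uniform position in a window.

    Returns the modified window and a record with 1-based ``pos``, the
    ``spacer``, and the planted ``text``.
    """
    if len(window) < model.max_span:
        raise ValueError(
            f"window of {len(window)} bp cannot host a {model.max_span} bp site"
        )
    text, spacer = _sample_site(model, rng)
    pos0 = int(rng.integers(0, len(window) - len(text) + 1))
    new_window = window[:pos0] + text + window[pos0 + len(text):]
    return new_window, {"pos": pos0 + 1, "spacer": spacer, "text": text}


def _rand_protein(rng: np.random.Generator, length: int) -> str:
    aas = np.array(list(AMINO_ACIDS))
    return "".join(rng.choice(aas, size=length))


class _RepliconBuilder:
    """Accumulates genes left to right on one random-background replicon."""

    def __init__(self, replicon_id: str, length: int, config: SimulationConfig,
                 rng: np.random.Generator):
        self.id = replicon_id
        self.length = length
        self.cfg = config
        self.rng = rng
        bases = np.array(list("ACGT"))
        self.seq = rng.choice(bases, size=length, p=config.background)
        self.cursor = 1 + int(rng.integers(*config.locus_gap_range))
        self.genes: list[GeneRecord] = []
        self.site_spans: list[tuple[int, int]] = []
        self._gene_counter = 0

    def _next_gene_id(self) -> str:
        self._gene_counter += 1
        return f"{self.id}_g{self._gene_counter:05d}"

    def place_gene(self, strand: str, role: str, product: str) -> GeneRecord:
        lo, hi = self.cfg.gene_length_range
        length = int(self.rng.integers(lo, hi + 1))
        start = self.cursor
        end = start + length - 1
        margin = max(max(self.cfg.locus_gap_range), self.cfg.upstream_window)
        if end > self.length - margin:
            raise ValueError(
                f"replicon {self.id} too short to host the requested loci"
            )
        gene = GeneRecord(
            gene_id=self._next_gene_id(), replicon_id=self.id,
            start=start, end=end, strand=strand, role=role, product=product,
        )
        self.genes.append(gene)
        self.cursor = end + 1
        return gene

    def advance(self, gap_range: tuple) -> None:
        self.cursor += int(self.rng.integers(gap_range[0], gap_range[1] + 1))

    def write_text(self, start: int, text: str) -> None:
        self.seq[start - 1 : start - 1 + len(text)] = list(text)

    def plant_for_gene(
        self, gene: GeneRecord, model: BipartiteMotifModel, window: int
    ) -> SiteTruth:
        """Plant one site inside `gene`'s upstream window (on its strand)."""
        text, spacer = _sample_site(model, self.rng)
        span = len(text)
        offset = int(self.rng.integers(0, window - span + 1))
        if gene.strand == "+":
            start = gene.start - window + offset
            end = start + span - 1
            minus35_start = start
        else:
            end = gene.end + window - offset
            start = end - span + 1
            minus35_start = end
        if start < 1 or end > self.length:
            raise ValueError(f"replicon {self.id} too short for promoter planting")
        self.write_text(start, text if gene.strand == "+" else reverse_complement(text))
        self.site_spans.append((start, end))
        return SiteTruth(
            replicon_id=self.id, strand=gene.strand, start=start, end=end,
            minus35_start=minus35_start, spacer=spacer, target_gene_id=gene.gene_id,
        )

    def plant_decoys(
        self, half_texts: tuple[str, str], max_span: int, rate_per_kb: float
    ) -> int:
        """Scatter isolated -35 or -10 half-sites across the replicon, never
        closer than one full site span to a planted site or another decoy,
        so no accidental bipartite site arises."""
        n = int(round(rate_per_kb * self.length / 1000.0))
        margin = max_span
        placed = 0
        guarded = list(self.site_spans)
        for _ in range(n):
            half = half_texts[0] if self.rng.random() < 0.5 else half_texts[1]
            strand = "+" if self.rng.random() < 0.5 else "-"
            pos = int(self.rng.integers(1, self.length - len(half) + 1))
            lo, hi = pos - margin, pos + len(half) - 1 + margin
            if any(lo <= e and hi >= s for s, e in guarded):
                continue  # would abut a real site or another decoy
            self.write_text(pos, half if strand == "+" else reverse_complement(half))
            guarded.append((pos, pos + len(half) - 1))
            placed += 1
        return placed


def _locus_layout(category: str, ecf_strand: str) -> list[tuple[str, str]]:
    """Left-to-right (role, strand) plan for one locus in forward coords."""
    other = "-" if ecf_strand == "+" else "+"
    if category == "ECF_alone":
        return [("ECF", ecf_strand)]
    if category == "COE_up_same":
        pair = [("COE", ecf_strand), ("ECF", ecf_strand)]
    elif category == "COE_down_same":
        pair = [("ECF", ecf_strand), ("COE", ecf_strand)]
    elif category == "convergent":  # >ECF> <COE<
        pair = [("ECF", ecf_strand), ("COE", other)]
    elif category == "divergent":  # <ECF< >COE>
        pair = [("COE", other), ("ECF", ecf_strand)]
    elif category == "ungrouped":
        pair = [("HYP", ecf_strand), ("ECF", ecf_strand)]
    else:
        raise ValueError(f"unknown category {category!r}")
    return pair if ecf_strand == "+" else pair[::-1]


def simulate(config: SimulationConfig, outdir=None) -> SyntheticDataset:
    """Generate genomes, annotations, domain table, proteins, and truth.

    Deterministic for a fixed ``config.seed``; writes the on-disk bundle to
    ``outdir`` when given.  Raises a sizing error when a replicon cannot
    host its share of loci.
    """
    rng = np.random.default_rng(config.seed)
    model = generator_motif_model(
        config.planted_minus35, config.planted_minus10, config.spacer_probs,
        config.site_mutation_rate, config.background,
    )

    categories = sorted(config.category_proportions)
    cat_draw = rng.choice(
        categories, size=config.n_ecf_loci,
        p=[config.category_proportions[c] for c in categories],
    )
    phyla = sorted(config.phylum_proportions)
    phylum_draw = rng.choice(
        phyla, size=config.n_ecf_loci,
        p=[config.phylum_proportions[p] for p in phyla],
    )
    # phylum ancestor proteins (WLPEP pinned in the sigma2-sigma4 linker)
    linker_at = config.protein_sigma2_end  # motif occupies linker start
    ancestors = {}
    for ph in phyla:
        seq = _rand_protein(rng, config.protein_length)
        ancestors[ph] = (
            seq[:linker_at] + LINKER_MOTIF + seq[linker_at + len(LINKER_MOTIF):]
        )

    builders = [
        _RepliconBuilder(f"repl_{i + 1:03d}", config.replicon_length, config, rng)
        for i in range(config.n_replicons)
    ]
    per_rep = np.array_split(np.arange(config.n_ecf_loci), config.n_replicons)

    genes: list[GeneRecord] = []
    domains: dict[str, list[str]] = {}
    proteins: dict[str, str] = {}
    architectures: dict[str, ArchitectureAnnotation] = {}
    loci: list[LocusTruth] = []
    sites: list[SiteTruth] = []

    for builder, locus_indices in zip(builders, per_rep):
        for li in locus_indices:
            category = str(cat_draw[li])
            phylum = str(phylum_draw[li])
            ecf_strand = "+" if rng.random() < 0.5 else "-"
            # a background gene always separates consecutive loci
            builder.place_gene(
                "+" if rng.random() < 0.5 else "-", "other",
                str(rng.choice(_BACKGROUND_PRODUCTS)),
            )
            builder.advance(config.locus_gap_range)

            layout = _locus_layout(category, ecf_strand)
            internal_gap = (
                config.divergent_gap_range if category == "divergent"
                else config.operon_gap_range
            )
            coe_class = (
                str(rng.choice(sorted(_COE_PRODUCTS)))
                if any(role == "COE" for role, _ in layout) else "none"
            )
            placed: dict[str, GeneRecord] = {}
            for k, (role, strand) in enumerate(layout):
                if k:
                    builder.advance(internal_gap)
                if role == "ECF":
                    gene = builder.place_gene(
                        strand, "ECF41", "ECF41 family RNA polymerase sigma factor"
                    )
                    domains[gene.gene_id] = ["Sigma70_r2", "Sigma70_r4"]
                elif role == "COE":
                    gene = builder.place_gene(strand, "other", _COE_PRODUCTS[coe_class])
                    domains[gene.gene_id] = [
                        str(rng.choice(_COE_DOMAIN_CHOICES[coe_class]))
                    ]
                else:  # HYP
                    gene = builder.place_gene(strand, "other", "hypothetical protein")
                    domains[gene.gene_id] = []
                placed[role] = gene
            builder.advance(config.locus_gap_range)

            # promoters: the shared region of a divergent pair is split in
            # half so the two sites cannot collide
            window_for = {
                role: (
                    min(config.upstream_window,
                        (internal_gap[0] // 2 if category == "divergent"
                         else config.upstream_window))
                )
                for role in placed
            }
            flags = {"ECF": False, "COE": None if "COE" not in placed else False}
            for role in ("ECF", "COE"):
                gene = placed.get(role)
                if gene is None:
                    continue
                p = config.promoter_occurrence.get((category, role), 0.0)
                if rng.random() < p:
                    sites.append(
                        builder.plant_for_gene(gene, model, window_for[role])
                    )
                    flags[role] = True

            # the ECF protein: phylum ancestor with within-phylum divergence,
            # linker motif kept intact
            ecf_gene = placed["ECF"]
            anc = ancestors[phylum]
            mutated = list(anc)
            protected = set(range(linker_at, linker_at + len(LINKER_MOTIF)))
            hit_positions = np.nonzero(
                rng.random(len(anc)) < config.within_phylum_divergence
            )[0]
            aas = np.array(list(AMINO_ACIDS))
            for pos in hit_positions:
                if pos not in protected:
                    mutated[pos] = str(rng.choice(aas))
            proteins[ecf_gene.gene_id] = "".join(mutated)
            architectures[ecf_gene.gene_id] = ArchitectureAnnotation(
                protein_id=ecf_gene.gene_id,
                sigma2_end=config.protein_sigma2_end,
                sigma4_end=config.protein_sigma4_end,
                extension_end=config.protein_length,
                source="provided",
            )

            loci.append(
                LocusTruth(
                    ecf_gene_id=ecf_gene.gene_id,
                    category=category,
                    partner_gene_id=(
                        placed["COE"].gene_id if "COE" in placed else None
                    ),
                    coe_class=coe_class,
                    phylum=phylum,
                    species=f"{phylum} sp{li + 1:04d}",
                    promoter_on_ecf=flags["ECF"],
                    promoter_on_coe=flags["COE"],
                )
            )
        builder.plant_decoys(
            (config.planted_minus35, config.planted_minus10),
            model.max_span,
            config.decoy_rate,
        )
        genes.extend(builder.genes)

    dataset = SyntheticDataset(
        config=config,
        replicons={b.id: "".join(b.seq) for b in builders},
        genes=genes,
        domains=domains,
        proteins=proteins,
        architectures=architectures,
        truth=SyntheticTruth(loci=loci, sites=sites, generator_model=model),
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset
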