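"""Synthetic restoration chronosequence with known ground truth.

Emulates the statistical structure of a grassland restoration study: six
grassland ages (1, 5, 10, 15, 25, 30 years since restoration), three plots
per age, three quadrats per plot (54 composite samples).  Two microbial
guilds — copiotrophs (r-strategists: many rRNA operon copies, strong
ribosomal codon bias, larger genomes) and oligotrophs (K-strategists: few
copies, weak bias) — mix along the gradient with a copiotroph weight π(age)
that increases with restoration age.  Every downstream input file (OTU
table, taxonomy, copy-number reference, coding-sequence FASTA, single-copy
gene hits, PLFA peaks, fumigation pairs, enzyme plates, GeoChip signals) is
emitted together with a ground-truth JSON, so each analysis stage can be
verified against planted parameter values.

Not simulated: raw sequencing reads with error profiles, phylogenies.  The
OTU abundance model is Dirichlet-multinomial (concentration 0.3 x guild
weight per taxon), which gives realistic overdispersion but no spatial or
temporal autocorrelation between plots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biomarkers import BIOMASS_K, DEFAULT_MARKER_MAP, INTERNAL_STANDARD
from .codon import SYNONYMOUS_FAMILIES

__all__ = [
    "GuildParams",
    "SampleDesign",
    "WorldConfig",
    "SyntheticWorld",
    "generate_design",
    "generate_world",
    "generate_codon_genes",
    "emit_datasets",
    "DEFAULT_GUILDS",
]


class InvalidDesignError(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GuildParams:
    """Trait distributions of one life-history guild."""

    name: str
    rrn_copies_range: tuple[int, int]
    genome_size_lognormal: tuple[float, float]  # (mu, sigma) of ln(bp)
    gc_mean_sd: tuple[float, float]
    ribo_bias_strength: float  # codon-preference exponent s; 0 = no bias
    plfa_signature: dict[str, float]
    phylum: str = "Unknownphyla"

    def __post_init__(self) -> None:
        lo, hi = self.rrn_copies_range
        if lo < 1 or hi < lo:
            raise ConfigError("rrn copy range must be positive and ordered")
        if not (0 < self.gc_mean_sd[0] < 1):
            raise ConfigError("GC mean must lie in (0, 1)")
        if self.ribo_bias_strength < 0:
            raise ConfigError("ribosomal bias strength must be nonnegative")


DEFAULT_GUILDS: tuple[GuildParams, GuildParams] = (
    GuildParams(
        name="copiotroph",
        rrn_copies_range=(5, 10),
        genome_size_lognormal=(np.log(5.0e6), 0.12),
        gc_mean_sd=(0.55, 0.03),
        ribo_bias_strength=2.0,
        plfa_signature={
            "gram_positive": 0.20,
            "gram_negative": 0.45,
            "fungal": 0.10,
            "general_bacterial": 0.25,
        },
        phylum="Proteobacteria",
    ),
    GuildParams(
        name="oligotroph",
        rrn_copies_range=(1, 2),
        genome_size_lognormal=(np.log(3.5e6), 0.12),
        gc_mean_sd=(0.62, 0.03),
        ribo_bias_strength=0.5,
        plfa_signature={
            "gram_positive": 0.40,
            "gram_negative": 0.20,
            "fungal": 0.30,
            "general_bacterial": 0.10,
        },
        phylum="Acidobacteria",
    ),
)

DEFAULT_AGES = (1, 5, 10, 15, 25, 30)


@dataclass(frozen=True)
class SampleDesign:
    """Chronosequence sampling layout: ages x plots x quadrats."""

    ages: tuple[int, ...]
    plots_per_age: int
    quadrats_per_plot: int

    @property
    def n_samples(self) -> int:
        return len(self.ages) * self.plots_per_age * self.quadrats_per_plot

    def sample_ids(self) -> list[tuple[str, int]]:
        """Composite sample ids ``age{Y}_p{P}_q{Q}`` paired with their age."""
        out = []
        for age in self.ages:
            for p in range(1, self.plots_per_age + 1):
                for q in range(1, self.quadrats_per_plot + 1):
                    out.append((f"age{age}_p{p}_q{q}", age))
        return out


def generate_design(
    ages: list[int] | tuple[int, ...] = DEFAULT_AGES,
    plots_per_age: int = 3,
    quadrats_per_plot: int = 3,
) -> SampleDesign:
    """Enumerate the composite samples of a chronosequence design."""
    if not ages or any(int(a) != a or a <= 0 for a in ages):
        raise InvalidDesignError("ages must be positive integers")
    if plots_per_age <= 0 or quadrats_per_plot <= 0:
        raise InvalidDesignError("plots and quadrats per plot must be positive")
    return SampleDesign(tuple(int(a) for a in ages), int(plots_per_age), int(quadrats_per_plot))


@dataclass
class WorldConfig:
    """All tunable knobs of the generator; every noise level is explicit.

    The study design values are fixed by the field layout; library size and
    per-guild richness are not stated by any field protocol and are exposed
    defaults, not asserted as faithful.
    """

    guilds: tuple[GuildParams, ...] = DEFAULT_GUILDS
    design: SampleDesign = field(default_factory=generate_design)
    taxa_per_guild: int = 100
    library_size: int = 20_000
    pi_start: float = 0.1  # copiotroph weight at the youngest age
    pi_end: float = 0.9  # ... at the oldest age
    dirichlet_alpha: float = 0.3
    # coding-sequence generation
    genes_per_genome: int = 60
    ribosomal_genes: int = 20
    gene_length_codons: int = 200
    # single-copy-gene emission
    scg_genes: int = 10
    scg_gene_length_bp: int = 900
    genome_equivalents: float = 1000.0
    # GC reads
    gc_reads_per_sample: int = 300
    gc_read_sd: float = 0.03
    # PLFA
    total_plfa_nmol_g: float = 80.0
    plfa_dry_mass_g: float = 5.0
    plfa_standard_amount_nmol: float = 100.0
    plfa_standard_area: float = 1.0e6
    plfa_noise_cv: float = 0.05
    # fumigation (endpoints at youngest/oldest age, mg kg^-1)
    biomass_endpoints: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"C": (340.0, 420.0), "N": (87.0, 115.0), "P": (19.2, 17.3)}
    )
    nonfumigated_base: dict[str, float] = field(
        default_factory=lambda: {"C": 150.0, "N": 25.0, "P": 12.0}
    )
    fumigation_noise_cv: float = 0.03
    # enzyme plates
    enzyme_endpoints: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"AP": (60.0, 140.0), "AG": (20.0, 60.0), "NAG": (15.0, 45.0)}
    )
    mub_standards_um: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)
    plate_slope: float = 120.0  # fluorescence units per µM MUB
    plate_control: float = 200.0
    plate_noise_sd: float = 2.0
    plate_incubation_h: float = 3.0
    plate_soil_equivalent_g: float = 0.01
    plate_well_volume_ml: float = 0.25
    # GeoChip
    geochip_probes: int = 120
    geochip_background: float = 100.0
    geochip_dropout: float = 0.15

    def __post_init__(self) -> None:
        if len(self.guilds) < 2:
            raise ConfigError("world needs at least two guilds")
        if self.taxa_per_guild <= 0 or self.library_size <= 0:
            raise ConfigError("taxa_per_guild and library_size must be positive")


def pi_of_age(age: float, config: WorldConfig) -> float:
    """Copiotroph mixing weight: linear in age between the design endpoints."""
    a0, a1 = min(config.design.ages), max(config.design.ages)
    if a1 == a0:
        return config.pi_start
    t = (age - a0) / (a1 - a0)
    return config.pi_start + (config.pi_end - config.pi_start) * t


@dataclass
class SyntheticWorld:
    """Ground-truth world: planted guild traits and realized compositions."""

    config: WorldConfig
    seed: int
    taxa: pd.DataFrame  # otu_id, taxonomy, guild, copies, genome_size, gc
    counts: pd.DataFrame  # otu_id x sample
    pi: pd.Series  # copiotroph weight per sample
    genes: dict[str, list[tuple[str, str, bool]]]  # guild -> (id, seq, is_ribosomal)
    codon_prefs: dict[str, np.ndarray]

    def sample_ages(self) -> pd.Series:
        return pd.Series(
            {s: int(s.split("_")[0][3:]) for s in self.counts.columns}, name="age"
        )

    def guild_read_fraction(self, guild: str) -> pd.Series:
        mask = (self.taxa["guild"] == guild).to_numpy()
        return self.counts.loc[mask].sum(axis=0) / self.counts.sum(axis=0)

    def true_weighted_copies(self) -> pd.Series:
        rel = self.counts / self.counts.sum(axis=0)
        return rel.mul(self.taxa["copies"].to_numpy(), axis=0).sum(axis=0)

    def true_mean_genome_size(self) -> pd.Series:
        rel = self.counts / self.counts.sum(axis=0)
        return rel.mul(self.taxa["genome_size"].to_numpy(), axis=0).sum(axis=0)

    def true_gc_mean(self) -> pd.Series:
        rel = self.counts / self.counts.sum(axis=0)
        return rel.mul(self.taxa["gc"].to_numpy(), axis=0).sum(axis=0)

    def true_plfa_fractions(self) -> pd.DataFrame:
        rows = {}
        for sample in self.counts.columns:
            w = self.pi[sample]
            classes = {}
            for i, g in enumerate(self.config.guilds):
                gw = w if g.name == "copiotroph" else (1 - w) / max(1, len(self.config.guilds) - 1)
                for cls, frac in g.plfa_signature.items():
                    classes[cls] = classes.get(cls, 0.0) + gw * frac
            total = sum(classes.values())
            rows[sample] = {c: v / total for c, v in classes.items()}
        return pd.DataFrame(rows).T

    def planted_biomass(self) -> pd.DataFrame:
        ages = self.sample_ages()
        a0, a1 = min(self.config.design.ages), max(self.config.design.ages)
        rows = {}
        for sample, age in ages.items():
            t = (age - a0) / (a1 - a0) if a1 > a0 else 0.0
            rows[sample] = {
                an: lo + (hi - lo) * t
                for an, (lo, hi) in self.config.biomass_endpoints.items()
            }
        return pd.DataFrame(rows).T

    def planted_activities(self) -> pd.DataFrame:
        ages = self.sample_ages()
        a0, a1 = min(self.config.design.ages), max(self.config.design.ages)
        rows = {}
        for sample, age in ages.items():
            t = (age - a0) / (a1 - a0) if a1 > a0 else 0.0
            rows[sample] = {
                enz: lo + (hi - lo) * t
                for enz, (lo, hi) in self.config.enzyme_endpoints.items()
            }
        return pd.DataFrame(rows).T


def generate_codon_genes(
    rng: np.random.Generator,
    codon_prefs: dict[str, np.ndarray],
    n_genes: int,
    bias_strength: float,
    gene_length_codons: int,
    id_prefix: str,
) -> list[tuple[str, str]]:
    """Random coding sequences with within-family codon weights ∝ exp(s·pref).

    ``codon_prefs`` holds one fixed preference vector per synonymous family;
    s = 0 yields uniform synonymous usage.
    """
    fams = list(SYNONYMOUS_FAMILIES)
    genes = []
    for g in range(n_genes):
        fam_idx = rng.integers(0, len(fams), size=gene_length_codons)
        codons = np.empty(gene_length_codons, dtype=object)
        for fi, fam in enumerate(fams):
            pos = np.nonzero(fam_idx == fi)[0]
            if pos.size == 0:
                continue
            w = np.exp(bias_strength * codon_prefs[fam])
            w = w / w.sum()
            codons[pos] = rng.choice(SYNONYMOUS_FAMILIES[fam], size=pos.size, p=w)
        genes.append((f"{id_prefix}_{g:03d}", "".join(codons)))
    return genes


def generate_world(config: WorldConfig | None = None, seed: int = 0) -> SyntheticWorld:
    """Draw a complete synthetic world; deterministic for a fixed seed."""
    config = config or WorldConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))

    # taxa with true traits
    records = []
    for guild in config.guilds:
        lo, hi = guild.rrn_copies_range
        mu, sigma = guild.genome_size_lognormal
        gcm, gcs = guild.gc_mean_sd
        for i in range(config.taxa_per_guild):
            genus = f"Genus_{guild.name}_{i:04d}"
            records.append(
                {
                    "otu_id": f"OTU_{guild.name[:3]}_{i:04d}",
                    "taxonomy": (
                        f"Bacteria;{guild.phylum};Class_{guild.name};"
                        f"Order_{guild.name};Family_{guild.name};{genus};{genus} sp."
                    ),
                    "guild": guild.name,
                    "copies": int(rng.integers(lo, hi + 1)),
                    "genome_size": float(rng.lognormal(mu, sigma)),
                    "gc": float(np.clip(rng.normal(gcm, gcs), 0.25, 0.75)),
                }
            )
    taxa = pd.DataFrame(records).set_index("otu_id")

    # per-sample Dirichlet-multinomial compositions
    samples = config.design.sample_ids()
    weights = {}
    counts = np.zeros((len(taxa), len(samples)), dtype=int)
    guild_weight_cols = []
    for j, (sample, age) in enumerate(samples):
        w_cop = pi_of_age(age, config)
        weights[sample] = w_cop
        n_other = len(config.guilds) - 1
        per_guild = {
            g.name: (w_cop if g.name == "copiotroph" else (1 - w_cop) / n_other)
            for g in config.guilds
        }
        alpha = np.array(
            [config.dirichlet_alpha * per_guild[g] for g in taxa["guild"]]
        )
        p = rng.dirichlet(alpha)
        counts[:, j] = rng.multinomial(config.library_size, p)
    counts_df = pd.DataFrame(
        counts, index=taxa.index, columns=[s for s, _ in samples]
    )

    # one fixed codon preference vector per family, shared by all guilds
    codon_prefs = {
        fam: rng.standard_normal(len(codons))
        for fam, codons in SYNONYMOUS_FAMILIES.items()
    }
    genes: dict[str, list[tuple[str, str, bool]]] = {}
    for guild in config.guilds:
        plain = generate_codon_genes(
            rng, codon_prefs, config.genes_per_genome, 0.0,
            config.gene_length_codons, f"{guild.name}_gene",
        )
        rib = generate_codon_genes(
            rng, codon_prefs, config.ribosomal_genes, guild.ribo_bias_strength,
            config.gene_length_codons, f"{guild.name}_rib",
        )
        genes[guild.name] = [(gid, seq, False) for gid, seq in plain] + [
            (gid, seq, True) for gid, seq in rib
        ]

    return SyntheticWorld(
        config=config,
        seed=int(seed),
        taxa=taxa,
        counts=counts_df,
        pi=pd.Series(weights, name="pi_copiotroph"),
        genes=genes,
        codon_prefs=codon_prefs,
    )


def _fmt(df: pd.DataFrame, path: Path, sep: str = "\t", index_label: str | None = None) -> None:
    df.to_csv(path, sep=sep, index=index_label is not None, index_label=index_label,
              float_format="%.17g", lineterminator="\n")


def emit_datasets(world: SyntheticWorld, outdir: str | Path) -> dict[str, Path]:
    """Write every downstream input file plus the ground-truth JSON.

    Deterministic for a fixed world: measurement noise is drawn from a
    generator seeded by the world seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = world.config
    rng = np.random.default_rng(np.random.SeedSequence([world.seed, 202]))
    paths: dict[str, Path] = {}

    def register(name: str, path: Path) -> Path:
        paths[name] = path
        return path

    # OTU table, taxonomy, copy-number reference
    _fmt(world.counts, register("otu_table", out / "otu_table.tsv"), index_label="otu_id")
    tax = world.taxa[["taxonomy"]]
    _fmt(tax, register("taxonomy", out / "taxonomy.tsv"), index_label="otu_id")
    ref = pd.DataFrame(
        {
            "taxon": [t.split(";")[5] for t in world.taxa["taxonomy"]],
            "copies": world.taxa["copies"].to_numpy(),
        }
    )
    _fmt(ref.set_index("taxon"), register("copy_numbers", out / "copy_numbers.tsv"),
         index_label="taxon")

    # coding sequences + ribosomal id list
    gdir = out / "genomes"
    gdir.mkdir(exist_ok=True)
    rib_ids = []
    for guild, genelist in world.genes.items():
        fasta = gdir / f"{guild}.fna"
        with open(fasta, "w", newline="\n") as fh:
            for gid, seq, is_rib in genelist:
                fh.write(f">{gid}\n{seq}\n")
                if is_rib:
                    rib_ids.append(gid)
        register(f"fasta_{guild}", fasta)
    with open(register("ribosomal_ids", out / "ribosomal_ids.txt"), "w", newline="\n") as fh:
        fh.write("\n".join(rib_ids) + "\n")

    # single-copy-gene hit tables: noiseless coverage == genome equivalents
    true_size = world.true_mean_genome_size()
    scg_rows = []
    bp_rows = []
    for sample in world.counts.columns:
        total_bp = cfg.genome_equivalents * true_size[sample]
        bp_rows.append({"sample": sample, "total_bp": total_bp})
        for g in range(cfg.scg_genes):
            scg_rows.append(
                {
                    "sample": sample,
                    "gene": f"scg_{g:02d}",
                    "length_bp": cfg.scg_gene_length_bp,
                    "aligned_bp": cfg.genome_equivalents * cfg.scg_gene_length_bp,
                }
            )
    _fmt(pd.DataFrame(scg_rows).set_index("sample"),
         register("scg_hits", out / "scg_hits.tsv"), index_label="sample")
    _fmt(pd.DataFrame(bp_rows).set_index("sample"),
         register("sample_bp", out / "sample_bp.tsv"), index_label="sample")

    # per-read GC fractions
    gc_mean = world.true_gc_mean()
    gc_rows = []
    for sample in world.counts.columns:
        reads = np.clip(
            rng.normal(gc_mean[sample], cfg.gc_read_sd, size=cfg.gc_reads_per_sample),
            0.0, 1.0,
        )
        gc_rows.extend({"sample": sample, "gc_fraction": v} for v in reads)
    _fmt(pd.DataFrame(gc_rows).set_index("sample"),
         register("gc_reads", out / "gc_reads.tsv"), index_label="sample")

    # PLFA peaks
    class_markers: dict[str, list[str]] = {}
    for marker, cls in DEFAULT_MARKER_MAP.items():
        class_markers.setdefault(cls, []).append(marker)
    fractions = world.true_plfa_fractions()
    area_per_nmol = cfg.plfa_standard_area / cfg.plfa_standard_amount_nmol
    plfa_rows = []
    meta_rows = []
    for sample in world.counts.columns:
        meta_rows.append(
            {
                "sample": sample,
                "internal_standard_amount_nmol": cfg.plfa_standard_amount_nmol,
                "dry_mass_g": cfg.plfa_dry_mass_g,
            }
        )
        plfa_rows.append(
            {"sample": sample, "marker": INTERNAL_STANDARD, "peak_area": cfg.plfa_standard_area}
        )
        for cls, markers in class_markers.items():
            conc = cfg.total_plfa_nmol_g * fractions.loc[sample, cls] / len(markers)
            for marker in markers:
                noise = rng.lognormal(0.0, cfg.plfa_noise_cv) if cfg.plfa_noise_cv > 0 else 1.0
                area = conc * cfg.plfa_dry_mass_g * area_per_nmol * noise
                plfa_rows.append({"sample": sample, "marker": marker, "peak_area": area})
    pd.DataFrame(plfa_rows).to_csv(register("plfa", out / "plfa.csv"),
                                   index=False, float_format="%.17g", lineterminator="\n")
    pd.DataFrame(meta_rows).to_csv(register("plfa_meta", out / "plfa_meta.csv"),
                                   index=False, float_format="%.17g", lineterminator="\n")

    # fumigation pairs
    biomass = world.planted_biomass()
    fum_rows = []
    for sample in world.counts.columns:
        for analyte, k in BIOMASS_K.items():
            base = cfg.nonfumigated_base[analyte]
            noise = rng.lognormal(0.0, cfg.fumigation_noise_cv) if cfg.fumigation_noise_cv > 0 else 1.0
            nonfum = base * noise
            fum = nonfum + biomass.loc[sample, analyte] * k
            fum_rows.append(
                {"sample": sample, "analyte": analyte,
                 "fumigated": fum, "nonfumigated": nonfum}
            )
    pd.DataFrame(fum_rows).to_csv(register("fumigation", out / "fumigation.csv"),
                                  index=False, float_format="%.17g", lineterminator="\n")

    # enzyme plates
    standards = {
        c: cfg.plate_slope * c
        + (rng.normal(0.0, cfg.plate_noise_sd) if cfg.plate_noise_sd > 0 else 0.0)
        for c in cfg.mub_standards_um
    }
    pd.DataFrame(
        {"concentration_uM": list(standards), "fluorescence": list(standards.values())}
    ).to_csv(register("enzyme_standards", out / "enzyme_standards.csv"),
             index=False, float_format="%.17g", lineterminator="\n")
    activities = world.planted_activities()
    well_rows = []
    for sample in world.counts.columns:
        for enz in cfg.enzyme_endpoints:
            a = activities.loc[sample, enz]
            mub_um = a * cfg.plate_soil_equivalent_g * cfg.plate_incubation_h / cfg.plate_well_volume_ml
            net = mub_um * cfg.plate_slope
            noise_t = rng.normal(0.0, cfg.plate_noise_sd) if cfg.plate_noise_sd > 0 else 0.0
            noise_c = rng.normal(0.0, cfg.plate_noise_sd) if cfg.plate_noise_sd > 0 else 0.0
            well_rows.append(
                {"sample": sample, "enzyme": enz,
                 "test": cfg.plate_control + net + noise_t,
                 "control": cfg.plate_control + noise_c}
            )
    pd.DataFrame(well_rows).to_csv(register("enzyme_wells", out / "enzyme_wells.csv"),
                                   index=False, float_format="%.17g", lineterminator="\n")

    # GeoChip matrices
    samples = list(world.counts.columns)
    probes = [f"probe_{i:04d}" for i in range(cfg.geochip_probes)]
    signal = rng.lognormal(np.log(2000.0), 0.6, size=(len(probes), len(samples)))
    dropout = rng.random(signal.shape) < cfg.geochip_dropout
    signal[dropout] = 0.0
    fold = rng.uniform(1.0, 6.0, size=signal.shape)
    background = np.where(signal > 0, signal / fold, cfg.geochip_background)
    snr = rng.uniform(0.5, 8.0, size=signal.shape)
    groups = {s: s.rsplit("_q", 1)[0] for s in samples}
    for name, arr in (("signal", signal), ("background", background), ("snr", snr)):
        _fmt(pd.DataFrame(arr, index=probes, columns=samples),
             register(f"geochip_{name}", out / f"geochip_{name}.tsv"), index_label="probe")
    _fmt(pd.DataFrame({"group": pd.Series(groups)}),
         register("geochip_groups", out / "geochip_groups.tsv"), index_label="sample")

    # ground truth
    truth = {
        "seed": world.seed,
        "pi_copiotroph": {s: float(v) for s, v in world.pi.items()},
        "weighted_rrn_copies": {s: float(v) for s, v in world.true_weighted_copies().items()},
        "mean_genome_size": {s: float(v) for s, v in true_size.items()},
        "gc_mean": {s: float(v) for s, v in gc_mean.items()},
        "plfa_class_fractions": {
            s: {c: float(v) for c, v in fractions.loc[s].items()} for s in fractions.index
        },
        "biomass_mg_kg": {s: {a: float(v) for a, v in biomass.loc[s].items()} for s in biomass.index},
        "enzyme_activity_nmol_g_h": {
            s: {e: float(v) for e, v in activities.loc[s].items()} for s in activities.index
        },
        "guild_by_otu": {o: g for o, g in world.taxa["guild"].items()},
        "copies_by_otu": {o: int(c) for o, c in world.taxa["copies"].items()},
        "ribo_bias_strength": {g.name: g.ribo_bias_strength for g in cfg.guilds},
    }
    with open(register("truth", out / "truth.json"), "w", newline="\n") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
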