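"""Synthetic study generator: two cryptic species pairs on a climate gradient.

Every pipeline stage can be exercised without field data: the generators
emulate the statistical structure the analyses assume — two-chemotype
logistic-normal CHC compositions, a two-clade COI alignment with island-model
population structure, allometric morphometric variation with technical
repeats, and a 19-variable climate table driven by one latent east-west
gradient with a logistic occurrence model. All generators are pure
functions of (config, seed); one global seed expands deterministically into
per-generator child seeds, and ground-truth labels are emitted throughout.
"""
from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import msprime
import numpy as np
import pandas as pd
from scipy.special import expit

from .morpho import MorphTable
from .popgen import Alignment
from .preprocess import PeakTable, Substance, parse_substance_name

#: sampling sites along the French Guiana east-west gradient: (code, lat, lon)
SITES: list[tuple[str, float, float]] = [
    ("AP", 5.200783, -54.312017),
    ("SL", 5.463902, -53.997322),
    ("AN", 5.409200, -53.650933),
    ("SI", 5.352035, -53.077604),
    ("PS", 5.061213, -52.988772),
    ("PAR", 5.265905, -52.933605),
    ("LN", 4.039650, -52.673933),
    ("KO", 5.083106, -52.643022),
    ("MT", 4.866000, -52.538483),
    ("CA", 4.557416, -52.463067),
    ("CAY", 4.793831, -52.317594),
    ("RE", 4.181286, -52.131963),
    ("PAT", 4.546067, -52.130483),
]

#: morphometric character codes (linear measurements, µm)
MORPHO_VARIABLES = [
    "HL", "HW", "EW", "EL", "SCL", "SCW", "ML", "MW", "PL", "PW",
    "PPL", "PPW", "FL", "FW", "TL", "CW", "CL", "GW", "SPL", "SPD",
    "PSL", "MOD", "CS",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the synthetic study.

    Defaults describe the reference scenario: 60 colonies per chemotype,
    40 CHC substances of which 10 markers differ by 2 clr units between
    chemotypes with 0.5 clr units of within-colony noise; a 449-bp COI
    alignment whose species clades differ at exactly 16 fixed SNPs, with
    island-model structure across 4 populations; 40 individuals per species
    measured twice on 20 characters; and a logistic occurrence model with
    slope 2 on the latent climate gradient.
    """

    # CHC block
    n_colonies_per_chemotype: int = 60
    n_substances: int = 40
    n_marker_substances: int = 10
    chemotype_shift: float = 2.0        # clr units on marker substances
    within_noise_sd: float = 0.5        # clr units
    detection_limit: float = 1e-4       # proportion of row total zeroed below
    # COI block
    seq_length: int = 449
    n_populations: int = 4
    fixed_snps_between_species: int = 16
    theta: float = 2.0                  # population-scaled mutation rate
    migration: float = 0.2              # in [0, 1]; 1 = panmixia
    # morphometrics block
    n_individuals_morpho: int = 40      # per species
    n_variables_morpho: int = 20
    shape_offset: float = 0.2           # log units on the offset variables
    n_shape_offset_vars: int = 3
    allometry_slope: float = 0.1
    size_sd: float = 0.1                # log units of isometric size
    morpho_noise_sd: float = 0.05       # log units, biological
    repeat_noise_sd: float = 0.02       # log units, technical repeats
    # environment block
    climate_slope: float = 2.0          # logistic coefficient on the gradient
    n_climate_vars: int = 19
    climate_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_colonies_per_chemotype": self.n_colonies_per_chemotype,
            "n_substances": self.n_substances,
            "n_marker_substances": self.n_marker_substances,
            "n_populations": self.n_populations,
            "n_individuals_morpho": self.n_individuals_morpho,
            "n_variables_morpho": self.n_variables_morpho,
            "n_climate_vars": self.n_climate_vars,
            "seq_length": self.seq_length,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_marker_substances > self.n_substances:
            raise ValueError("n_marker_substances cannot exceed n_substances")
        if self.within_noise_sd <= 0:
            raise ValueError("within_noise_sd must be > 0")
        if not 0.0 <= self.migration <= 1.0:
            raise ValueError("migration must lie in [0, 1]")
        if self.fixed_snps_between_species >= self.seq_length:
            raise ValueError("fixed_snps_between_species must be < seq_length")
        if self.n_populations > len(SITES):
            raise ValueError(f"at most {len(SITES)} populations supported")
        if self.n_variables_morpho > len(MORPHO_VARIABLES):
            raise ValueError(f"at most {len(MORPHO_VARIABLES)} morphometric variables")

    def child_seed(self, name: str) -> int:
        """Deterministic per-generator seed below 2**31."""
        h = zlib.crc32(name.encode())
        ss = np.random.SeedSequence([self.seed, h])
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)

    def to_dict(self) -> dict:
        return asdict(self)


def colony_frame(config: ScenarioConfig) -> pd.DataFrame:
    """Colony ids, ground-truth species and site assignment (deterministic).

    The first ``n_colonies_per_chemotype`` colonies are species A, the rest
    species B; sites rotate round-robin within each species so every
    population holds both species. Coordinates are the site's, with a small
    seeded jitter so colonies are distinct points.
    """
    n = config.n_colonies_per_chemotype
    rng = np.random.default_rng(config.child_seed("colonies"))
    sites = SITES[: config.n_populations]
    rows = []
    for i in range(2 * n):
        species = "A" if i < n else "B"
        code, lat, lon = sites[i % config.n_populations]
        rows.append(
            {
                "colony": f"COL{i + 1:03d}",
                "species": species,
                "population": code,
                "lat": lat + rng.normal(0, 0.02),
                "lon": lon + rng.normal(0, 0.02),
            }
        )
    return pd.DataFrame(rows).set_index("colony")


def _substance_pool() -> list[str]:
    """Candidate shorthand names cycling over classes and odd chain lengths."""
    templates = [
        "C{c}",             # n-alkane
        "13-MeC{c}",        # monomethyl
        "13,23-DiMeC{c}",   # dimethyl
        "C{c}:1",           # alkene
        "C{c}:2",           # alkadiene
        "3,7,11-TriMeC{c}",  # trimethyl
        "13-MeC{c}:1",      # methyl-branched alkene
        "C{c}:3",           # alkatriene
    ]
    chains = list(range(25, 42, 2))
    names = []
    for t_i, template in enumerate(templates):
        for c in chains:
            names.append(template.format(c=c))
    # interleave classes so small tables still cover many classes
    out = []
    for j in range(len(chains)):
        for t_i in range(len(templates)):
            out.append(names[t_i * len(chains) + j])
    return out


def gen_chc_profiles(config: ScenarioConfig) -> PeakTable:
    """Two-chemotype logistic-normal CHC peak table.

    Per-chemotype mean log-abundances differ by ``chemotype_shift`` on the
    marker substances; colony profiles add iid N(0, within_noise_sd) noise on
    the log scale. Values below ``detection_limit`` of the row total are
    zeroed to exercise zero handling downstream. The ground-truth chemotype
    is recorded in the sample metadata.
    """
    rng = np.random.default_rng(config.child_seed("chc"))
    frame = colony_frame(config)
    names = _substance_pool()[: config.n_substances]
    substances = []
    for i, nm in enumerate(names):
        s = parse_substance_name(nm)
        s.retention_time = 10.0 + 0.9 * (s.chain_length - 25) + 0.07 * (i % 8)
        substances.append(s)

    mu = rng.normal(0.0, 1.5, size=config.n_substances)
    markers = rng.choice(
        config.n_substances, size=config.n_marker_substances, replace=False
    )
    mu_b = mu.copy()
    mu_b[markers] += config.chemotype_shift

    n = config.n_colonies_per_chemotype
    logs = np.empty((2 * n, config.n_substances))
    logs[:n] = mu + rng.normal(0, config.within_noise_sd, size=(n, config.n_substances))
    logs[n:] = mu_b + rng.normal(0, config.within_noise_sd, size=(n, config.n_substances))
    ab = np.exp(logs)
    ab /= ab.sum(axis=1, keepdims=True)
    ab[ab < config.detection_limit] = 0.0

    meta = frame.copy()
    meta["genus"] = "Crematogaster"
    meta = meta.rename(columns={"species": "chemotype", "population": "location"})
    abundance = pd.DataFrame(ab, index=frame.index, columns=[s.id for s in substances])
    pt = PeakTable(abundance, substances, meta)
    pt.abundance.attrs["marker_substances"] = [substances[i].id for i in sorted(markers)]
    return pt


def _mutate_backbone(
    seqs: dict[str, np.ndarray],
    ts,
    site_map: np.ndarray,
    sample_ids: list[str],
    backbone_seq: np.ndarray,
) -> None:
    """Overlay msprime mutations onto backbone sequences (in place)."""
    for var in ts.variants():
        pos = site_map[int(var.site.position)]
        anc = var.site.ancestral_state
        backbone = backbone_seq[pos]
        mapping = {}
        pool = [b for b in "ACGT" if b != backbone]
        for allele in var.alleles:
            if allele is None:
                continue
            if allele == anc:
                mapping[allele] = backbone
            else:
                mapping[allele] = pool.pop(0) if pool else backbone
        for g, sid in zip(var.genotypes, sample_ids):
            seqs[sid][pos] = mapping[var.alleles[g]]


def _simulate_clade(
    config: ScenarioConfig,
    sample_counts: dict[str, int],
    seed: int,
):
    """msprime island-model genealogy + mutations for one species clade."""
    pops = list(sample_counts)
    panmictic = config.migration >= 0.999 or len(pops) == 1
    dem = msprime.Demography()
    if panmictic:
        dem.add_population(name="POOL", initial_size=1.0)
        samples = [
            msprime.SampleSet(sum(sample_counts.values()), population="POOL", ploidy=1)
        ]
    else:
        for p in pops:
            dem.add_population(name=p, initial_size=1.0)
        dem.add_population(name="ANC", initial_size=1.0)
        if config.migration > 0:
            rate = 4.0 * config.migration / (1.0 - config.migration)
            dem.set_symmetric_migration_rate(pops, rate / max(len(pops) - 1, 1))
        dem.add_population_split(time=20.0, derived=pops, ancestral="ANC")
        samples = [
            msprime.SampleSet(c, population=p, ploidy=1)
            for p, c in sample_counts.items()
        ]
    L_eff = config.seq_length - config.fixed_snps_between_species
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=1,
        sequence_length=L_eff,
        discrete_genome=True,
        random_seed=(seed % (2**31 - 2)) + 1,
    )
    mu = config.theta / (2.0 * L_eff)
    mts = msprime.sim_mutations(
        ts,
        rate=mu,
        model=msprime.JC69(),
        discrete_genome=True,
        random_seed=((seed + 1) % (2**31 - 2)) + 1,
    )
    return mts


def gen_coi_alignment(config: ScenarioConfig) -> tuple[Alignment, pd.DataFrame]:
    """Two-clade COI alignment plus the sample -> population/species map.

    One random ancestral sequence; the two species clades differ at exactly
    ``fixed_snps_between_species`` sites. Within-species variation comes
    from a neutral island-model coalescent (``n_populations`` demes,
    symmetric migration mapped from the ``migration`` knob, an ancestral
    merge guaranteeing coalescence), so the site-frequency spectrum is
    quasi-neutral; ``theta`` is the expected pairwise diversity of a
    panmictic clade. ``migration=1`` collapses the demes into one pool.
    """
    rng = np.random.default_rng(config.child_seed("coi"))
    frame = colony_frame(config)
    L = config.seq_length
    bases = np.array(list("ACGT"))
    ancestral = bases[rng.integers(0, 4, size=L)]

    fixed_sites = rng.choice(L, size=config.fixed_snps_between_species, replace=False)
    site_map = np.setdiff1d(np.arange(L), fixed_sites)  # msprime coord -> column

    backbone = {"A": ancestral.copy(), "B": ancestral.copy()}
    for s in fixed_sites:
        alternatives = [b for b in "ACGT" if b != ancestral[s]]
        backbone["B"][s] = rng.choice(alternatives)

    seqs: dict[str, np.ndarray] = {}
    for species in ("A", "B"):
        ids = frame.index[frame["species"] == species].tolist()
        pops = frame.loc[ids, "population"]
        counts: dict[str, int] = {}
        ordered_ids: list[str] = []
        for p in pd.unique(pops):
            members = [i for i in ids if frame.loc[i, "population"] == p]
            counts[p] = len(members)
            ordered_ids.extend(members)
        for sid in ordered_ids:
            seqs[sid] = backbone[species].copy()
        mts = _simulate_clade(
            config, counts, seed=int(rng.integers(0, 2**30))
        )
        _mutate_backbone(seqs, mts, site_map, ordered_ids, backbone[species])

    ids = frame.index.tolist()
    aln = Alignment(ids, ["".join(seqs[i]) for i in ids])
    popmap = frame[["population", "species"]].copy()
    return aln, popmap


def gen_morphometrics(config: ScenarioConfig) -> MorphTable:
    """Allometric log-normal measurements with two technical repeats.

    log x = baseline + isometric size + species shape offset (on a fixed
    subset of variables) + allometry (size-dependent term on the last
    variable) + biological noise; each repeat adds technical noise.
    """
    rng = np.random.default_rng(config.child_seed("morpho"))
    p = config.n_variables_morpho
    variables = MORPHO_VARIABLES[:p]
    offset_vars = variables[: config.n_shape_offset_vars]
    allo_var = variables[-1]
    baseline = np.log(300.0) + rng.normal(0, 0.5, size=p)

    n = config.n_individuals_morpho
    sites = [s[0] for s in SITES[: config.n_populations]]
    rows = []
    for i in range(2 * n):
        species = "A" if i < n else "B"
        ind = f"IND{i + 1:03d}"
        location = sites[i % len(sites)]
        size = rng.normal(0, config.size_sd)
        log_true = baseline + size
        if species == "B":
            for v in offset_vars:
                log_true[variables.index(v)] += config.shape_offset
        log_true[variables.index(allo_var)] += config.allometry_slope * size
        log_true = log_true + rng.normal(0, config.morpho_noise_sd, size=p)
        for rep in (1, 2):
            log_obs = log_true + rng.normal(0, config.repeat_noise_sd, size=p)
            for j, v in enumerate(variables):
                rows.append(
                    {
                        "individual": ind,
                        "repeat": rep,
                        "variable": v,
                        "value": float(np.exp(log_obs[j])),
                        "species": species,
                        "location": location,
                    }
                )
    mt = MorphTable(pd.DataFrame(rows))
    mt.long.attrs["shape_offset_variables"] = offset_vars
    mt.long.attrs["allometry_variable"] = allo_var
    return mt


def gen_env_table(config: ScenarioConfig) -> pd.DataFrame:
    """Climate, canopy, plant and partner covariates per colony.

    Colonies sit on a longitude axis; one latent standardized gradient
    (high = east = wetter/cooler) drives all ``n_climate_vars`` correlated
    climate variables (temperature-like columns load negatively,
    precipitation-like ones positively) plus the focal species' occurrence
    through a logistic model with coefficient ``climate_slope``. Canopy,
    plant presence and partner identity carry no effect. The latent
    gradient is kept as ground truth.
    """
    rng = np.random.default_rng(config.child_seed("env"))
    n = 2 * config.n_colonies_per_chemotype
    lon = rng.uniform(-54.4, -52.1, size=n)
    lat = rng.uniform(4.0, 5.5, size=n)
    g = (lon - lon.mean()) / lon.std()

    k = config.n_climate_vars
    n_temp = min(11, k)
    loadings = rng.uniform(0.7, 1.3, size=k)
    loadings[:n_temp] *= -1.0  # temperature block: cooler where wetter
    climate = g[:, None] * loadings[None, :] + rng.normal(
        0, config.climate_noise_sd, size=(n, k)
    )

    occ_p = expit(config.climate_slope * g)
    species = np.where(rng.random(n) < occ_p, "PS", "PAT")
    partner = np.where(rng.random(n) < 0.5, "A", "B")
    canopy = rng.beta(5.0, 2.0, size=n)
    plants = {
        f"plant_{nm}": rng.binomial(1, pr, size=n)
        for nm, pr in zip(
            ["Philodendron", "Aechmea", "Codonanthe", "Peperomia", "Anthurium"],
            [0.5, 0.4, 0.3, 0.35, 0.25],
        )
    }

    out = pd.DataFrame(
        {
            "lon": lon,
            "lat": lat,
            "latent_gradient": g,
            **{f"bio{j + 1:02d}": climate[:, j] for j in range(k)},
            "canopy": canopy,
            **plants,
            "partner": partner,
            "species": species,
        },
        index=[f"COL{i + 1:03d}" for i in range(n)],
    )
    out.index.name = "colony"
    return out


def write_inputs(config: ScenarioConfig, outdir: str | Path) -> dict[str, str]:
    """Generate and write every pipeline input; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": str(outdir / "chc_peaks.csv"),
        "annotations": str(outdir / "chc_substances.csv"),
        "sample_meta": str(outdir / "chc_samples.csv"),
        "alignment": str(outdir / "coi.fasta"),
        "popmap": str(outdir / "popmap.csv"),
        "morphometrics": str(outdir / "morphometrics.csv"),
        "environment": str(outdir / "environment.csv"),
    }
    pt = gen_chc_profiles(config)
    pt.write(paths["peaks"], paths["annotations"], paths["sample_meta"])
    aln, popmap = gen_coi_alignment(config)
    aln.to_fasta(paths["alignment"])
    popmap.to_csv(paths["popmap"], index_label="sample")
    gen_morphometrics(config).write_csv(paths["morphometrics"])
    gen_env_table(config).to_csv(paths["environment"])
    return paths
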