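"""Synthetic survey generator with planted, recoverable structure.

The generator emulates a two-season oligotrophic surface survey:

* station metadata (temperature, salinity, Chl a) drawn from seasonal
  normals whose means and SDs default to the survey's printed statistics;
* bacterial abundance coupled to Chl a, production proportional to abundance
  (times lognormal noise), and respiration driven by the abundance of one
  planted community module — independent of production — so the
  coupled/decoupled structure the linkage stage should detect is known;
* an ASV count table in which module members share a per-sample latent
  factor on the log-abundance scale, giving controllable intra-module
  Spearman correlation, plus chloroplast/mitochondria contaminant lineages
  and uneven sequencing depths so the filtering and rarefaction paths are
  exercised;
* raw tracer inputs back-computed by exactly inverting the rate formulas, so
  the rate stage reproduces the true panel and the whole pipeline can be
  tested end-to-end against ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gyremet import conet, io, rates

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "Bundle",
    "gen_environment",
    "gen_rates",
    "gen_community",
    "gen_dataset",
    "write_dataset",
]

SEASONS = ("summer", "winter")

#: (phylum, class, order) pool for non-contaminant lineages, echoing the taxa
#: that dominate oligotrophic surface communities.
TAXON_POOL = (
    ("Proteobacteria", "Alphaproteobacteria", "SAR11_clade"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales"),
    ("Proteobacteria", "Alphaproteobacteria", "Puniceispirillales"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhodospirillales"),
    ("Proteobacteria", "Alphaproteobacteria", "Rickettsiales"),
    ("Proteobacteria", "Gammaproteobacteria", "SAR86_clade"),
    ("Proteobacteria", "Gammaproteobacteria", "Thiotrichales"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales"),
    ("Proteobacteria", "Gammaproteobacteria", "Coxiellales"),
    ("Bacteroidota", "Bacteroidia", "Flavobacteriales"),
    ("Cyanobacteria", "Cyanobacteriia", "Synechococcales"),
    ("Actinobacteriota", "Actinobacteria", "Microtrichales"),
    ("Planctomycetota", "Planctomycetes", "Pirellulales"),
    ("Marinimicrobia_SAR406_clade", "Marinimicrobia", "Marinimicrobiales"),
)

CHLOROPLAST_LINEAGE = ("Bacteria", "Cyanobacteria", "Cyanobacteriia", "Chloroplast", "", "")
MITOCHONDRIA_LINEAGE = (
    "Bacteria",
    "Proteobacteria",
    "Alphaproteobacteria",
    "Rickettsiales",
    "Mitochondria",
    "",
)


def _season_dict(summer: float, winter: float) -> dict:
    return {"summer": summer, "winter": winter}


@dataclass
class GeneratorConfig:
    """All tunable knobs of the generator; defaults are the survey conditions.

    Environmental and abundance means/SDs default to the printed seasonal
    statistics of the study region (temperature °C, salinity, Chl a µg L⁻¹,
    BA cells mL⁻¹).  ``ba_chl_slope`` couples abundance to Chl a;
    ``cs_bp`` (fg C cell⁻¹ d⁻¹) with lognormal noise couples production to
    abundance; ``br_module_effect`` (β, mg C m⁻³ d⁻¹ per z-unit) drives
    respiration from the first planted module's z-scored abundance,
    independent of production.
    """

    seed: int = 0
    n_summer: int = 40
    n_winter: int = 48

    temperature_mean: dict = field(default_factory=lambda: _season_dict(29.8, 26.9))
    temperature_sd: dict = field(default_factory=lambda: _season_dict(0.6, 1.4))
    salinity_mean: dict = field(default_factory=lambda: _season_dict(34.7, 34.8))
    salinity_sd: dict = field(default_factory=lambda: _season_dict(0.4, 0.5))
    chl_mean: dict = field(default_factory=lambda: _season_dict(0.05, 0.10))
    chl_sd: dict = field(default_factory=lambda: _season_dict(0.02, 0.04))
    ba_mean: dict = field(default_factory=lambda: _season_dict(6.95e5, 8.45e5))
    ba_sd: dict = field(default_factory=lambda: _season_dict(1.49e5, 1.13e5))

    ba_chl_slope: float = 3.0e6  # cells mL^-1 per ug Chl L^-1
    cs_bp: float = 0.085  # fg C cell^-1 d^-1
    cs_bp_lognoise: float = 0.35  # SD of log-scale noise on BP
    br_baseline: float = 4.7  # mg C m^-3 d^-1
    br_module_effect: float = 1.0  # beta: mg C m^-3 d^-1 per z-unit of module 1
    br_noise_sd: float = 1.2  # mg C m^-3 d^-1
    bacterial_fraction_range: tuple = (0.4, 0.8)  # INT_0.2-0.8 / INT_T

    n_asv: int = 120
    module_sizes: tuple = (15, 12, 10)
    intra_module_rho: float = 0.85  # target pairwise correlation inside modules
    asv_lognoise: float = 1.0  # SD of idiosyncratic log-abundance noise
    base_abundance_sd: float = 1.0  # SD of per-ASV log baseline
    depth_range: tuple = (50_000, 120_000)  # sequencing depth, uniform
    contaminant_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("temperature_sd", "salinity_sd", "chl_sd", "ba_sd"):
            if any(v < 0 for v in getattr(self, name).values()):
                raise ValueError(f"{name} must be non-negative")
        if any(size < 2 for size in self.module_sizes):
            raise ValueError("every planted module needs >= 2 ASVs")
        if sum(self.module_sizes) > self.n_asv:
            raise ValueError("module sizes exceed n_asv")
        if not (0 < self.intra_module_rho < 1):
            raise ValueError("intra_module_rho must lie in (0, 1)")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("depth_range must be positive and ordered")
        if not (0 <= self.contaminant_fraction < 1):
            raise ValueError("contaminant_fraction must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        d["bacterial_fraction_range"] = list(self.bacterial_fraction_range)
        d["depth_range"] = list(self.depth_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        for key in ("module_sizes", "bacterial_fraction_range", "depth_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class SyntheticTruth:
    """Planted structure stored alongside every generated dataset."""

    membership: dict  # asv_id -> module label (0 = background)
    coefficients: dict  # couplings actually used
    latent_factors: dict  # module label (str) -> per-sample factor values
    module1_z: dict  # sample_id -> realized module-1 z-score abundance
    truncations: dict  # counts of values clipped into their valid range

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))


@dataclass
class Bundle:
    metadata: pd.DataFrame
    rate_inputs: pd.DataFrame
    true_panel: pd.DataFrame
    asv_table: pd.DataFrame
    taxonomy: pd.DataFrame
    truth: SyntheticTruth


def _sample_ids(config: GeneratorConfig) -> tuple[list, list]:
    summer = [f"SU{i + 1:02d}" for i in range(config.n_summer)]
    winter = [f"WI{i + 1:02d}" for i in range(config.n_winter)]
    return summer, winter


def gen_environment(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Station metadata: season, temperature, salinity, Chl a (clipped at 0)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    summer_ids, winter_ids = _sample_ids(config)
    records = []
    for season, ids in (("summer", summer_ids), ("winter", winter_ids)):
        n = len(ids)
        temp = rng.normal(config.temperature_mean[season], config.temperature_sd[season], n)
        sal = rng.normal(config.salinity_mean[season], config.salinity_sd[season], n)
        chl = rng.normal(config.chl_mean[season], config.chl_sd[season], n)
        for sid, t, s, c in zip(ids, temp, sal, chl):
            records.append(
                {
                    "sample_id": sid,
                    "season": season,
                    "temperature": max(t, 0.0),
                    "salinity": max(s, 0.0),
                    "chl_a": max(c, 0.0),
                }
            )
    return pd.DataFrame(records).set_index("sample_id")


def gen_community(
    metadata: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict, dict]:
    """ASV count table with planted correlated modules plus taxonomy.

    Log-abundance of ASV i in sample s is ``base_i + λ·F_{m(i),s} + ε`` where
    members of a module share the latent factor F_m and λ is set from the
    target intra-module correlation (λ² / (λ² + σ²) = rho).  Rows are
    converted to proportions and sampled multinomially at a per-sample depth.

    Returns (table, taxonomy, membership, latent_factors).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_samples = len(metadata)
    n_asv = config.n_asv
    asv_ids = [f"ASV{i + 1:04d}" for i in range(n_asv)]

    membership = {a: 0 for a in asv_ids}
    cursor = 0
    for label, size in enumerate(config.module_sizes, start=1):
        for a in asv_ids[cursor : cursor + size]:
            membership[a] = label
        cursor += size

    n_contam = round(config.contaminant_fraction * n_asv)
    if cursor + n_contam > n_asv:
        raise ValueError("not enough background ASVs for the contaminant fraction")
    contaminants = asv_ids[n_asv - n_contam :]  # background tail carries the contaminant labels

    lam = math.sqrt(config.intra_module_rho / (1 - config.intra_module_rho)) * config.asv_lognoise
    base = rng.normal(0.0, config.base_abundance_sd, n_asv)
    factors = {
        label: rng.normal(0.0, 1.0, n_samples)
        for label in range(1, len(config.module_sizes) + 1)
    }
    loga = np.tile(base, (n_samples, 1))
    module_of = np.array([membership[a] for a in asv_ids])
    for label, f in factors.items():
        loga[:, module_of == label] += lam * f[:, None]
    loga += rng.normal(0.0, config.asv_lognoise, size=(n_samples, n_asv))

    prop = np.exp(loga - loga.max(axis=1, keepdims=True))
    prop /= prop.sum(axis=1, keepdims=True)
    lo, hi = config.depth_range
    depths = rng.integers(lo, hi + 1, size=n_samples)
    counts = np.vstack([rng.multinomial(d, p) for d, p in zip(depths, prop)])

    table = pd.DataFrame(counts, index=metadata.index.copy(), columns=pd.Index(asv_ids, name="asv_id"))

    tax_rows = []
    pool_idx = rng.integers(0, len(TAXON_POOL), size=n_asv)
    for i, asv in enumerate(asv_ids):
        if asv in contaminants:
            lineage = CHLOROPLAST_LINEAGE if (i % 2 == 0) else MITOCHONDRIA_LINEAGE
        else:
            phylum, cls, order = TAXON_POOL[pool_idx[i]]
            lineage = ("Bacteria", phylum, cls, order, f"{order}_fam", "")
        tax_rows.append(dict(zip(io.RANKS, lineage)))
    taxonomy = pd.DataFrame(tax_rows, index=pd.Index(asv_ids, name="asv_id"))

    latent = {str(k): v.tolist() for k, v in factors.items()}
    return table, taxonomy, membership, latent


def _module1_z(table: pd.DataFrame, membership: dict) -> pd.Series:
    members = {a: 1 for a, m in membership.items() if m == 1}
    if not members:
        raise ValueError("no module-1 ASVs planted")
    return conet.module_abundance(table, members)["module_1"]


def gen_rates(
    metadata: pd.DataFrame,
    config: GeneratorConfig,
    module1_z: pd.Series,
    rng: np.random.Generator | None = None,
    constants: rates.ConversionConstants = rates.DEFAULT_CONSTANTS,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """True rate panel plus back-computed raw tracer inputs.

    BA = ba_mean(season) + slope·(Chl − chl_mean(season)) + noise;
    BP = csBP·BA·exp(ε); BR = BR₀ + β·z₁ + noise, with z₁ the realized
    module-1 z-score abundance, so BR is independent of BP given the module.
    Leucine and INT inputs invert the rate formulas exactly.

    Returns (rate_inputs, true_panel, truncation counts).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    truncations = {"ba": 0, "br": 0}
    input_rows = []
    panel_rows = []
    for sid, row in metadata.iterrows():
        season = row["season"]
        # residual noise keeps the seasonal BA SD near its target after the
        # Chl-driven component is accounted for
        resid_var = config.ba_sd[season] ** 2 - (config.ba_chl_slope * config.chl_sd[season]) ** 2
        resid_sd = math.sqrt(max(resid_var, (0.2 * config.ba_sd[season]) ** 2))
        ba = (
            config.ba_mean[season]
            + config.ba_chl_slope * (row["chl_a"] - config.chl_mean[season])
            + rng.normal(0.0, resid_sd)
        )
        if ba < 1e4:
            ba = 1e4
            truncations["ba"] += 1

        bp = config.cs_bp * ba / 1e6 * math.exp(rng.normal(0.0, config.cs_bp_lognoise))
        br = (
            config.br_baseline
            + config.br_module_effect * float(module1_z.loc[sid])
            + rng.normal(0.0, config.br_noise_sd)
        )
        if br < 0.05:
            br = 0.05
            truncations["br"] += 1

        leu = bp / constants.leu_to_c
        frac = rng.uniform(*config.bacterial_fraction_range)
        br_o2 = br / (constants.rq * constants.c_atomic_mass)
        cr_o2 = br_o2 / frac
        int_total = 10.0 ** ((math.log10(cr_o2) - constants.cal_intercept) / constants.cal_slope)
        int_02_08 = frac * int_total

        input_rows.append(
            {
                "sample_id": sid,
                "leu_incorporation": leu,
                "int_total": int_total,
                "int_02_08": int_02_08,
                "abs_sample": np.nan,
                "abs_blank": np.nan,
                "ba": ba,
            }
        )
        panel_rows.append(
            {
                "sample_id": sid,
                "bp": bp,
                "cr_o2": cr_o2,
                "br": br,
                "cs_bp": rates.cell_specific(bp, ba),
                "cs_br": rates.cell_specific(br, ba),
            }
        )
    return pd.DataFrame(input_rows), pd.DataFrame(panel_rows), truncations


def gen_dataset(config: GeneratorConfig) -> Bundle:
    """Generate a complete, mutually consistent dataset from one seed."""
    rng = np.random.default_rng(config.seed)
    metadata = gen_environment(config, rng)
    table, taxonomy, membership, latent = gen_community(metadata, config, rng)
    z1 = _module1_z(table, membership)
    rate_inputs, true_panel, truncations = gen_rates(metadata, config, z1, rng)
    truth = SyntheticTruth(
        membership=membership,
        coefficients={
            "ba_chl_slope": config.ba_chl_slope,
            "cs_bp": config.cs_bp,
            "br_baseline": config.br_baseline,
            "br_module_effect": config.br_module_effect,
        },
        latent_factors=latent,
        module1_z={sid: float(v) for sid, v in z1.items()},
        truncations=truncations,
    )
    # add BA to metadata for downstream correlation panels
    metadata = metadata.join(rate_inputs.set_index("sample_id")["ba"].rename("ba"))
    return Bundle(metadata, rate_inputs, true_panel, table, taxonomy, truth)


def write_dataset(bundle: Bundle, out_dir: str | Path) -> dict:
    """Write the bundle in the pipeline's input formats; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": out / "metadata.tsv",
        "rates": out / "rates.tsv",
        "asv": out / "asv.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "truth": out / "truth.json",
    }
    io.write_metadata(bundle.metadata, paths["metadata"])
    inputs = bundle.rate_inputs.rename(
        columns={v: k for k, v in io.RATES_INPUT_COLUMNS.items()}
    )
    inputs.to_csv(paths["rates"], sep="\t", index=False, na_rep="NA")
    io.write_asv_table(bundle.asv_table, paths["asv"])
    io.write_taxonomy(bundle.taxonomy, paths["taxonomy"])
    paths["truth"].write_text(bundle.truth.to_json() + "\n")
    return {k: str(v) for k, v in paths.items()}
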