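"""Synthetic cropland survey generator with recoverable ground truth.

Emulates a two-crop (maize/rice) soil survey so that every downstream stage
has a known target:

* site covariates drawn from the surveyed ranges (growing-season
  precipitation 450-1200 mm, temperature 4.6-10.3 °C) with crop-dependent
  soil chemistry;
* amino sugars and fumigation-extract TOCs back-solved from target
  bacterial/fungal necromass C and biomass C, so the carbon-pool formulas
  recover the intended pools exactly;
* ASV count tables per domain from a compound model — log-normal latent
  abundances with block-diagonal correlation (to induce co-occurrence
  network structure) and a per-taxon crop log-fold shift, then a multinomial
  draw at a fixed library size;
* SOC as a linear combination of the Z-scores of the twelve predictors plus
  Gaussian noise, mapped onto a g/kg scale by one global affine transform.

Four of the twelve predictors (bacterial/fungal Shannon diversity, network
PC1/PC2) are latent per-site attributes here: the generator stores the exact
values it fed into SOC, rather than re-deriving them from its own count
tables, so coefficient-recovery tests have an exact design matrix.  All
randomness flows from one integer seed through a named generator.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .soc_models import PREDICTOR_NAMES

LIBRARY_SIZE = 20_000

SITE_COLUMNS = (
    "site_id", "crop", "mgp", "mgt", "ph", "swc", "tn", "tp", "np_ratio",
    "ap", "glun", "galn", "mura", "toc_fum", "toc_unfum", "soc",
)

_BACTERIAL_PHYLA = (
    "Proteobacteria", "Actinobacteria", "Acidobacteria", "Chloroflexi",
    "Bacteroidota", "Gemmatimonadota",
)
_FUNGAL_PHYLA = ("Ascomycota", "Basidiomycota", "Mortierellomycota", "Chytridiomycota")


@dataclass(frozen=True)
class SiteRecord:
    """One sampled field: crop label, climate, soil chemistry, biomarkers, SOC."""

    site_id: str
    crop: str           # maize | rice
    mgp: float          # growing-season precipitation, mm
    mgt: float          # growing-season temperature, °C
    ph: float
    swc: float          # soil water content, fraction
    tn: float           # total N, g/kg
    tp: float           # total P, g/kg
    np_ratio: float
    ap: float           # available P, mg/kg
    glun: float         # glucosamine, mg/g
    galn: float         # galactosamine, mg/g
    mura: float         # muramic acid, mg/g
    toc_fum: float      # fumigated extract TOC, mg C/g
    toc_unfum: float    # unfumigated extract TOC, mg C/g
    soc: float          # g/kg


@dataclass
class AsvCounts:
    """Sites × taxa integer count matrix for one domain (or a merged table)."""

    matrix: np.ndarray
    taxa_ids: list[str]
    taxonomy: list[str]
    sample_ids: list[str]
    domain: str  # bacteria | fungi | merged
    taxon_domains: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("count matrix must be 2-D (sites x taxa)")
        if not np.issubdtype(self.matrix.dtype, np.integer):
            if not np.all(self.matrix == np.round(self.matrix)):
                raise ValueError("count matrix must be integer-valued")
            self.matrix = self.matrix.astype(np.int64)
        if np.any(self.matrix < 0):
            raise ValueError("counts must be non-negative")
        if self.matrix.shape != (len(self.sample_ids), len(self.taxa_ids)):
            raise ValueError("matrix shape does not match sample/taxa ids")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.taxa_ids)

    def relative_abundance(self) -> np.ndarray:
        totals = self.matrix.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError("zero-sum sample in count table")
        return self.matrix / totals


@dataclass
class GroundTruth:
    """Generating parameters: SOC coefficients, community shifts, correlation blocks.

    ``soc_coefficients`` maps each of the twelve predictors to its
    standardized effect (missing names mean 0).  ``crop_composition_shift``
    gives per-taxon log-fold offsets (rice minus maize) per domain.
    ``block_structure`` lists (block size, within-block correlation) pairs
    allocated sequentially over the merged taxon list.  SOC in g/kg is
    ``soc_location + soc_scale * (Σ coef·z + noise)``.
    """

    soc_coefficients: dict[str, float]
    crop_composition_shift: dict[str, np.ndarray]
    block_structure: list[tuple[int, float]]
    noise_sd: float = 0.7
    seed: int = 0
    n_bacteria: int = 120
    n_fungi: int = 60
    library_size: int = LIBRARY_SIZE
    soc_location: float = 14.0
    soc_scale: float = 5.0
    latent_sd: float = 1.2

    def __post_init__(self) -> None:
        unknown = set(self.soc_coefficients) - set(PREDICTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown predictor(s) in soc_coefficients: {sorted(unknown)}")
        for name, v in self.soc_coefficients.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite coefficient for {name!r}")
        if not math.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be finite and >= 0")
        for size, rho in self.block_structure:
            if size < 2:
                raise ValueError(f"block sizes must be >= 2, got {size}")
            if not (0.0 < rho < 1.0):
                raise ValueError(f"within-block correlation must be in (0, 1), got {rho}")
        for dom, arr in self.crop_composition_shift.items():
            arr = np.asarray(arr, float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite crop shift for domain {dom!r}")
            self.crop_composition_shift[dom] = arr

    def full_coefficients(self) -> pd.Series:
        return pd.Series(
            {name: float(self.soc_coefficients.get(name, 0.0)) for name in PREDICTOR_NAMES}
        )


@dataclass
class SurveyDataset:
    """A generated survey: site table, two count tables, predictors, truth echo."""

    sites: pd.DataFrame
    bacteria: AsvCounts
    fungi: AsvCounts
    predictors: pd.DataFrame  # the realized 12-column design that generated SOC
    truth: GroundTruth

    def site_records(self) -> list[SiteRecord]:
        return [SiteRecord(**{k: row[k] for k in SITE_COLUMNS}) for _, row in self.sites.iterrows()]


def default_ground_truth(seed: int = 0) -> GroundTruth:
    """Study-condition defaults: four nonzero SOC effects, ten correlated blocks.

    Coefficients {mnc: 0.4, mbc: 0.2, np_ratio: 0.3, net_pc1: 0.2}, residual
    SD 0.7 on the standardized scale; crop shifts ~ N(0, 0.6), centered, on a
    random half of the taxa.
    """
    rng = np.random.default_rng(seed)
    n_b, n_f = 120, 60
    shifts = {}
    for dom, n_taxa in (("bacteria", n_b), ("fungi", n_f)):
        s = rng.normal(0.0, 0.6, n_taxa)
        s[rng.random(n_taxa) < 0.5] = 0.0
        shifts[dom] = s - s.mean()
    return GroundTruth(
        soc_coefficients={"mnc": 0.4, "mbc": 0.2, "np_ratio": 0.3, "net_pc1": 0.2},
        crop_composition_shift=shifts,
        block_structure=[(8, 0.85)] * 10,
        noise_sd=0.7,
        seed=seed,
        n_bacteria=n_b,
        n_fungi=n_f,
    )


def _truncated_normal(rng, mean, sd, low, high, size):
    """Draw N(mean, sd) and resample out-of-range values (bounds are wide)."""
    x = rng.normal(mean, sd, size)
    bad = (x < low) | (x > high)
    while np.any(bad):
        x[bad] = rng.normal(mean, sd, bad.sum()) if np.isscalar(mean) else rng.normal(
            np.broadcast_to(mean, x.shape)[bad], np.broadcast_to(sd, x.shape)[bad]
        )
        bad = (x < low) | (x > high)
    return x


def _latent_abundances(rng, n_sites, n_taxa, blocks, sigma, base_mu, shift, is_rice):
    """Log-normal latents with block-factor correlation and crop shift."""
    eps = rng.normal(0.0, 1.0, (n_sites, n_taxa))
    start = 0
    for size, rho in blocks:
        stop = min(start + size, n_taxa)
        if stop - start < 2:
            break
        f = rng.normal(0.0, 1.0, n_sites)
        eps[:, start:stop] = (
            math.sqrt(rho) * f[:, None] + math.sqrt(1.0 - rho) * eps[:, start:stop]
        )
        start = stop
        if start >= n_taxa:
            break
    log_x = base_mu[None, :] + shift[None, :] * is_rice[:, None] + sigma * eps
    return np.exp(log_x)


def generate_survey(
    n_maize: int = 349,
    n_rice: int = 119,
    truth: GroundTruth | None = None,
    seed: int | None = None,
    *,
    with_counts: bool = True,
) -> SurveyDataset:
    """Generate a full synthetic survey (default 349 maize + 119 rice sites).

    Reproducible: the same (truth, seed) yields bit-identical output.  When
    ``seed`` is None the truth's own seed is used.  ``with_counts=False``
    skips the ASV tables (drawn last, so the site table is unchanged) —
    useful for regression-only replicates.
    """
    if n_maize < 4 or n_rice < 4:
        raise ValueError("need at least 4 sites per crop")
    if truth is None:
        truth = default_ground_truth(seed if seed is not None else 0)
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    n = n_maize + n_rice
    is_rice = np.concatenate([np.zeros(n_maize), np.ones(n_rice)])
    crop = np.where(is_rice == 1, "rice", "maize")

    # climate from the surveyed ranges; chemistry crop-shifted, clipped wide
    mgp = rng.uniform(450.0, 1200.0, n)
    mgt = rng.uniform(4.6, 10.3, n)
    ph = _truncated_normal(rng, np.where(is_rice, 6.0, 6.4), 0.7, 4.0, 9.0, n)
    swc = _truncated_normal(rng, np.where(is_rice, 0.35, 0.20), 0.05, 0.02, 0.60, n)
    tn = _truncated_normal(rng, np.where(is_rice, 1.6, 1.2), 0.35, 0.2, 4.0, n)
    tp = _truncated_normal(rng, np.where(is_rice, 0.55, 0.62), 0.15, 0.15, 1.5, n)
    np_ratio = tn / tp
    ap = _truncated_normal(rng, np.where(is_rice, 18.0, 25.0), 7.0, 1.0, 80.0, n)

    # microbial C pools: targets first, raw measurements back-solved
    mbc = _truncated_normal(rng, np.where(is_rice, 0.21, 0.13), np.where(is_rice, 0.09, 0.06), 0.01, 0.8, n)
    bnc = _truncated_normal(rng, np.where(is_rice, 1.01, 1.22), np.where(is_rice, 0.53, 0.42), 0.05, 4.0, n)
    fnc = _truncated_normal(rng, np.where(is_rice, 2.91, 3.49), np.where(is_rice, 0.89, 1.24), 0.05, 10.0, n)
    mnc = bnc + fnc
    from .carbon_pools import (
        BNC_FACTOR, FNC_FACTOR, MBC_CONVERSION_FACTOR, MW_GLUCOSAMINE, MW_MURAMIC_ACID,
    )
    mura = bnc / BNC_FACTOR
    glun = fnc / (MW_GLUCOSAMINE * FNC_FACTOR) * MW_GLUCOSAMINE + 2.0 * mura * MW_GLUCOSAMINE / MW_MURAMIC_ACID
    galn = rng.uniform(0.2, 1.2, n)
    toc_unfum = rng.uniform(0.15, 0.45, n)
    toc_fum = toc_unfum + MBC_CONVERSION_FACTOR * mbc

    # latent community predictors (exact SOC design values; maize more diverse)
    bact_sh = rng.normal(np.where(is_rice, 6.1, 6.5), 0.3)
    fung_sh = rng.normal(np.where(is_rice, 3.4, 3.8), 0.4)
    net_pc1 = rng.normal(0.0, 1.0, n)
    net_pc2 = rng.normal(0.0, 1.0, n)

    predictors = pd.DataFrame(
        {
            "mgp": mgp, "mgt": mgt, "ph": ph, "np_ratio": np_ratio, "ap": ap,
            "swc": swc, "mbc": mbc, "mnc": mnc, "bacterial_shannon": bact_sh,
            "fungal_shannon": fung_sh, "net_pc1": net_pc1, "net_pc2": net_pc2,
        }
    )[list(PREDICTOR_NAMES)]

    coefs = truth.full_coefficients()
    z = (predictors - predictors.mean()) / predictors.std(ddof=1)
    soc_std = z.to_numpy() @ coefs.to_numpy() + truth.noise_sd * rng.normal(0.0, 1.0, n)
    soc = truth.soc_location + truth.soc_scale * soc_std
    soc = np.clip(soc, 0.3, None)  # SOC must stay positive; clip is far in the tail

    site_ids = [f"S{i + 1:04d}" for i in range(n)]
    sites = pd.DataFrame(
        {
            "site_id": site_ids, "crop": crop, "mgp": mgp, "mgt": mgt, "ph": ph,
            "swc": swc, "tn": tn, "tp": tp, "np_ratio": np_ratio, "ap": ap,
            "glun": glun, "galn": galn, "mura": mura, "toc_fum": toc_fum,
            "toc_unfum": toc_unfum, "soc": soc,
        }
    )
    predictors.index = pd.Index(site_ids, name="site_id")

    if not with_counts:
        empty = AsvCounts(np.zeros((0, 0), np.int64), [], [], [], "bacteria")
        import dataclasses as _dc

        return SurveyDataset(sites, empty, _dc.replace(empty, domain="fungi"), predictors, truth)

    counts = {}
    for dom, n_taxa, phyla in (
        ("bacteria", truth.n_bacteria, _BACTERIAL_PHYLA),
        ("fungi", truth.n_fungi, _FUNGAL_PHYLA),
    ):
        shift = truth.crop_composition_shift.get(dom)
        if shift is None:
            shift = np.zeros(n_taxa)
        if len(shift) != n_taxa:
            raise ValueError(f"crop shift for {dom} has length {len(shift)}, expected {n_taxa}")
        base_mu = rng.normal(0.0, 1.5, n_taxa)
        lam = _latent_abundances(
            rng, n, n_taxa, truth.block_structure, truth.latent_sd, base_mu, shift, is_rice
        )
        probs = lam / lam.sum(axis=1, keepdims=True)
        mat = np.vstack([rng.multinomial(truth.library_size, probs[i]) for i in range(n)])
        prefix = "B" if dom == "bacteria" else "F"
        counts[dom] = AsvCounts(
            matrix=mat,
            taxa_ids=[f"{prefix}ASV{j + 1:04d}" for j in range(n_taxa)],
            taxonomy=[phyla[j % len(phyla)] for j in range(n_taxa)],
            sample_ids=site_ids,
            domain=dom,
        )

    return SurveyDataset(sites, counts["bacteria"], counts["fungi"], predictors, truth)


# ---------------------------------------------------------------------------
# fixtures I/O

def _biom_json(counts: AsvCounts) -> dict:
    """Minimal dense BIOM-format (1.0-style) JSON for one count table."""
    return {
        "id": f"micronet-{counts.domain}",
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "micronet",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [len(counts.taxa_ids), len(counts.sample_ids)],
        "rows": [
            {"id": t, "metadata": {"taxonomy": tax}}
            for t, tax in zip(counts.taxa_ids, counts.taxonomy)
        ],
        "columns": [{"id": s, "metadata": None} for s in counts.sample_ids],
        "data": counts.matrix.T.tolist(),
    }


def write_fixtures(dataset: SurveyDataset, directory: str | Path, *, biom: bool = False) -> dict:
    """Write a dataset to ``directory``; returns the manifest (also saved).

    Emits sites.tsv, counts_bacteria.tsv, counts_fungi.tsv, taxonomy.tsv and
    ground_truth.json (5 files); ``biom=True`` adds BIOM-style JSON count
    tables.  Refuses empty datasets before touching the filesystem.
    """
    if len(dataset.sites) == 0:
        raise ValueError("refusing to write an empty site table")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []

    def _write(name: str, writer) -> None:
        path = directory / name
        try:
            writer(path)
        except OSError as exc:
            raise OSError(f"failed writing fixture file {path}: {exc}") from exc
        files.append(name)

    _write("sites.tsv", lambda p: dataset.sites.to_csv(p, sep="\t", index=False))
    for counts in (dataset.bacteria, dataset.fungi):
        _write(
            f"counts_{counts.domain}.tsv",
            lambda p, c=counts: c.to_dataframe().to_csv(p, sep="\t", index_label="site_id"),
        )
    taxonomy = pd.DataFrame(
        {
            "taxon_id": dataset.bacteria.taxa_ids + dataset.fungi.taxa_ids,
            "domain": ["bacteria"] * len(dataset.bacteria.taxa_ids)
            + ["fungi"] * len(dataset.fungi.taxa_ids),
            "taxonomy": dataset.bacteria.taxonomy + dataset.fungi.taxonomy,
        }
    )
    _write("taxonomy.tsv", lambda p: taxonomy.to_csv(p, sep="\t", index=False))

    truth = dataset.truth
    truth_payload = {
        "soc_coefficients": truth.soc_coefficients,
        "crop_composition_shift": {k: v.tolist() for k, v in truth.crop_composition_shift.items()},
        "block_structure": [list(b) for b in truth.block_structure],
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "n_bacteria": truth.n_bacteria,
        "n_fungi": truth.n_fungi,
        "library_size": truth.library_size,
        "soc_location": truth.soc_location,
        "soc_scale": truth.soc_scale,
        "latent_sd": truth.latent_sd,
        "latent_predictors": {
            name: dataset.predictors[name].tolist()
            for name in ("bacterial_shannon", "fungal_shannon", "net_pc1", "net_pc2")
        },
    }
    _write("ground_truth.json", lambda p: p.write_text(json.dumps(truth_payload, indent=1)))

    if biom:
        for counts in (dataset.bacteria, dataset.fungi):
            _write(
                f"counts_{counts.domain}.biom.json",
                lambda p, c=counts: p.write_text(json.dumps(_biom_json(c))),
            )

    manifest = {"files": files, "seed": truth.seed, "n_sites": len(dataset.sites)}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_counts_tsv(path: str | Path, domain: str, taxonomy: dict[str, str] | None = None) -> AsvCounts:
    df = pd.read_csv(path, sep="\t", index_col="site_id")
    taxa = list(df.columns)
    return AsvCounts(
        matrix=df.to_numpy(),
        taxa_ids=taxa,
        taxonomy=[taxonomy.get(t, "unknown") if taxonomy else "unknown" for t in taxa],
        sample_ids=list(df.index.astype(str)),
        domain=domain,
    )


def read_fixtures(directory: str | Path) -> SurveyDataset:
    """Read back a fixture directory written by :func:`write_fixtures`."""
    directory = Path(directory)
    sites = pd.read_csv(directory / "sites.tsv", sep="\t")
    taxonomy_df = pd.read_csv(directory / "taxonomy.tsv", sep="\t")
    tax_map = dict(zip(taxonomy_df["taxon_id"], taxonomy_df["taxonomy"]))
    bacteria = read_counts_tsv(directory / "counts_bacteria.tsv", "bacteria", tax_map)
    fungi = read_counts_tsv(directory / "counts_fungi.tsv", "fungi", tax_map)
    payload = json.loads((directory / "ground_truth.json").read_text())
    latent = payload.pop("latent_predictors")
    payload["crop_composition_shift"] = {
        k: np.asarray(v, float) for k, v in payload["crop_composition_shift"].items()
    }
    payload["block_structure"] = [tuple(b) for b in payload["block_structure"]]
    truth = GroundTruth(**payload)
    predictors = sites.set_index("site_id")[
        ["mgp", "mgt", "ph", "np_ratio", "ap", "swc", "soc"]
    ].copy()
    from .carbon_pools import pools_table

    pools = pools_table(sites).set_index("site_id")
    predictors["mbc"] = pools["mbc"]
    predictors["mnc"] = pools["mnc"]
    for name, values in latent.items():
        predictors[name] = values
    predictors = predictors[list(PREDICTOR_NAMES)]
    return SurveyDataset(sites, bacteria, fungi, predictors, truth)
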