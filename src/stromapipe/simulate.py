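"""Synthetic study generator with known ground truth.

Every input the pipeline consumes can be generated here: hexagonal spot
grids over blob-like multi-class tissue masks, negative-binomial spot counts
driven by per-spot cell-type composition with stroma-loaded marker genes,
Beer-Lambert two-stain trichrome images, promoter methylation beta values
anti-correlated with expression, patient-clustered bulk expression, and
expression-dependent relapse times.  A full study is a pure function of
(config, seed): identical arguments regenerate identical data.

The generative models deliberately mirror the assumptions of the analysis
stages (NB counts with mean/dispersion parameterization, a random patient
intercept in bulk expression, exponential relapse times) so that recovery
tests have well-defined truth; they are not intended to reproduce the visual
texture of real tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from skimage.filters import gaussian

from . import io as spio
from .config import DEFAULT_BLUE, DEFAULT_PINK, PipelineConfig
from .io import MaskRaster, SpotGeometry
from .stains import StainBasis, od_to_rgb

CELL_TYPES = ("fibroblast", "smooth_muscle", "epithelium_normal",
              "epithelium_cancer", "lymphocyte")

#: Dirichlet parameters of cell-type composition per annotation class.
DEFAULT_COMPOSITIONS: dict[str, tuple[float, ...]] = {
    # (fibro, smooth muscle, normal epi, cancer epi, lymphocyte)
    "stroma": (10.0, 6.0, 1.0, 0.5, 1.0),
    "non-cancer gland": (1.0, 0.5, 14.0, 0.2, 1.0),
    "GG1": (2.0, 1.0, 1.0, 12.0, 1.0),
    "GG2": (2.0, 1.0, 1.0, 12.0, 1.0),
    "GG3": (1.5, 0.8, 0.8, 14.0, 1.0),
    "GG4": (1.5, 0.8, 0.8, 14.0, 1.0),
    "GG5": (1.5, 0.8, 0.8, 14.0, 1.0),
    "lymphocytes": (1.5, 0.5, 1.0, 0.5, 12.0),
    "lumen": (2.0, 1.0, 4.0, 1.0, 1.0),
}


@dataclass
class TissueTruth:
    """Generative ground truth for one simulated tissue section."""

    class_rasters: dict[str, MaskRaster]
    cell_type_signatures: pd.DataFrame  # type x gene mean expression per cell
    class_compositions: dict[str, np.ndarray]
    marker_genes: dict[str, dict]  # gene -> {cell_type, expected log2FC ...}
    dispersion: pd.Series  # per gene
    pixel_size: float

    def expected_class_mean(self, cls: str, mean_cells: float) -> pd.Series:
        """Expected gene means for a spot of a class (over the Dirichlet)."""
        alpha = np.asarray(self.class_compositions[cls], float)
        pi = alpha / alpha.sum()
        return pd.Series(
            mean_cells * (pi @ self.cell_type_signatures.to_numpy()),
            index=self.cell_type_signatures.columns,
        )


@dataclass
class SimulatedStudy:
    """Everything the pipeline consumes, plus the generative truth."""

    cfg: PipelineConfig
    seed: int
    samples: list[str]
    spots: dict[str, list[SpotGeometry]]
    masks: dict[str, dict[str, MaskRaster]]
    counts: dict[str, pd.DataFrame]
    cell_counts: dict[str, pd.Series]
    trichrome: dict[str, np.ndarray]
    stroma_masks: dict[str, MaskRaster]
    collagen_truth: dict[str, float]
    celltype_fractions: dict[str, pd.DataFrame]
    bulk: pd.DataFrame
    methylation_betas: pd.DataFrame
    methylation_regions: pd.Series
    survival: pd.DataFrame
    truth: dict = field(default_factory=dict)
    tissue_truth: TissueTruth | None = None


# ---------------------------------------------------------------------------
# geometry and masks
# ---------------------------------------------------------------------------

def make_spot_grid(
    width_um: float,
    height_um: float,
    spacing_um: float = 200.0,
    diameter_um: float = 55.0,
) -> list[SpotGeometry]:
    """Hexagonal spot lattice clipped to a rectangle.

    Rows are spacing * sqrt(3)/2 apart; odd rows are offset by spacing/2, so
    every spot's nearest neighbour sits exactly one spacing away.
    """
    if width_um <= 0 or height_um <= 0:
        raise ValueError("tissue dimensions must be positive")
    if not spacing_um > diameter_um > 0:
        raise ValueError("need spacing > diameter > 0")
    pitch = spacing_um * np.sqrt(3.0) / 2.0
    spots = []
    k = 0
    while (y := k * pitch) <= height_um + 1e-9:
        x0 = spacing_um / 2.0 if k % 2 else 0.0
        j = 0
        while (x := x0 + j * spacing_um) <= width_um + 1e-9:
            spots.append(
                SpotGeometry(
                    spot_id=f"spot_{len(spots):04d}",
                    center_x=x,
                    center_y=y,
                    diameter=diameter_um,
                    row=k,
                    col=j,
                )
            )
            j += 1
        k += 1
    return spots


def make_tissue_masks(
    shape: tuple[int, int],
    classes: Sequence[str],
    seed: int,
    proportions: Sequence[float] | None = None,
    pixel_size: float = 5.0,
    smooth_sigma: float = 20.0,
) -> dict[str, MaskRaster]:
    """Blob-like class rasters forming an exact partition of the image.

    A Gaussian-smoothed noise field is rank-transformed to uniform and cut at
    the cumulative class proportions, so each pixel belongs to exactly one
    class and the requested area proportions are met exactly (up to one
    pixel) while regions stay contiguous and blob-like.
    """
    rng = np.random.default_rng(seed)
    if proportions is None:
        proportions = [1.0 / len(classes)] * len(classes)
    p = np.asarray(proportions, float)
    if len(p) != len(classes) or np.any(p < 0):
        raise ValueError("proportions must be non-negative, one per class")
    p = p / p.sum()
    field_ = gaussian(rng.normal(size=shape), sigma=smooth_sigma, preserve_range=True)
    ranks = field_.ravel().argsort().argsort()  # 0 .. N-1
    u = (ranks + 0.5) / ranks.size
    edges = np.concatenate([[0.0], np.cumsum(p)])
    edges[-1] = 1.0
    out = {}
    for cls, lo, hi in zip(classes, edges[:-1], edges[1:]):
        m = ((u >= lo) & (u < hi)).reshape(shape)
        out[cls] = MaskRaster(mask=m, pixel_size=pixel_size)
    return out


# ---------------------------------------------------------------------------
# spot counts
# ---------------------------------------------------------------------------

def make_signatures(
    n_genes: int = 300,
    seed: int = 0,
    marker_name: str = "STROMARK",
    partner_names: tuple[str, ...] = ("ECMPART1", "ECMPART2"),
    marker_log2fc: float = 4.0,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Cell-type x gene mean-expression signatures with planted markers.

    The stroma marker and its ECM partners load on fibroblasts with a
    configured log2 enrichment over other cell types; remaining genes get
    lognormal baseline means with mild random type-specific variation.  The
    default enrichment, combined with the default class compositions, puts
    the marker's spot-level stroma-vs-gland log2 fold change near 2, the
    scale reported for strongly stroma-enriched transcripts in prostate
    tissue.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    base = rng.lognormal(mean=-1.0, sigma=1.0, size=n_genes)
    sig = np.outer(np.ones(len(CELL_TYPES)), base)
    sig *= rng.lognormal(mean=0.0, sigma=0.25, size=sig.shape)
    df = pd.DataFrame(sig, index=list(CELL_TYPES), columns=genes)
    markers: dict[str, dict] = {}
    for i, name in enumerate([marker_name, *partner_names]):
        gene = genes[i]
        df.rename(columns={gene: name}, inplace=True)
        df[name] = 0.3
        df.loc["fibroblast", name] = 0.3 * 2.0**marker_log2fc
        markers[name] = {"cell_type": "fibroblast", "log2_enrichment": marker_log2fc}
    # a cancer-epithelium marker for contrast analyses
    cancer_gene = df.columns[len(markers)]
    df.rename(columns={cancer_gene: "CANMARK"}, inplace=True)
    df["CANMARK"] = 0.3
    df.loc["epithelium_cancer", "CANMARK"] = 0.3 * 2.0**marker_log2fc
    markers["CANMARK"] = {"cell_type": "epithelium_cancer", "log2_enrichment": marker_log2fc}
    return df, markers


def sample_nb(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean mu, dispersion phi) via gamma-Poisson; Poisson when phi ~ 0."""
    mu = np.asarray(mu, float)
    phi = np.broadcast_to(np.asarray(phi, float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = phi < 1e-12
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    if (~tiny).any():
        lam = rng.gamma(shape=1.0 / phi[~tiny], scale=mu[~tiny] * phi[~tiny])
        out[~tiny] = rng.poisson(lam)
    return out


def simulate_counts(
    spots: Sequence[SpotGeometry],
    truth: TissueTruth,
    seed: int,
    mean_cells: float = 21.0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """NB spot counts from cell-type composition under the tissue masks.

    For each spot: its dominant mask class sets the Dirichlet prior of the
    cell-type composition pi_s; the cell count is shifted Poisson (>= 1) with
    the given mean; gene means are mu_gs = n_s * sum_t pi_st * signature_tg
    and counts are NB(mu, phi_g).

    Returns (counts genes x spots, cell counts, true dominant class).
    """
    from .annotation import spot_class_fractions

    rng = np.random.default_rng(seed)
    sig = truth.cell_type_signatures.to_numpy()
    genes = truth.cell_type_signatures.columns
    phi = truth.dispersion.reindex(genes).to_numpy(float)
    cols, ccs, dom = [], [], []
    counts = np.zeros((len(genes), len(spots)), dtype=np.int64)
    for si, spot in enumerate(spots):
        f = spot_class_fractions(spot, truth.class_rasters)
        cls = max(truth.class_compositions, key=lambda c: f.get(c))
        alpha = np.asarray(truth.class_compositions[cls], float)
        pi = np.zeros_like(alpha)
        pos = alpha > 0  # zero-weight cell types are exactly absent
        pi[pos] = rng.dirichlet(alpha[pos])
        n_cells = 1 + rng.poisson(max(mean_cells - 1.0, 0.0))
        mu = n_cells * (pi @ sig)
        counts[:, si] = sample_nb(rng, mu, phi)
        cols.append(spot.spot_id)
        ccs.append(n_cells)
        dom.append(cls)
    return (
        pd.DataFrame(counts, index=genes, columns=cols),
        pd.Series(ccs, index=cols, name="cell_count"),
        pd.Series(dom, index=cols, name="true_class"),
    )


# ---------------------------------------------------------------------------
# trichrome images
# ---------------------------------------------------------------------------

def simulate_trichrome(
    shape: tuple[int, int],
    collagen_fraction: float,
    seed: int,
    stain_vectors=(DEFAULT_BLUE, DEFAULT_PINK),
    pixel_size: float = 0.55,
    threshold: float = 0.20,
    blue_conc: float = 0.7,
    background_conc: float = 0.02,
    smooth_sigma: float = 8.0,
) -> tuple[np.ndarray, MaskRaster, float]:
    """Two-stain Beer-Lambert trichrome image with known collagen fraction.

    A smoothed random field over the stroma is cut at the collagen quantile:
    below the cut pixels are collagen (blue stain), above it muscle (pink
    stain), so exactly 1 - collagen_fraction of stroma pixels carry a pink
    concentration above ``threshold``.  The muscle pink concentration is
    placed symmetrically around the threshold (background + 2 * (threshold -
    background)) so that boundary smoothing at quantification time moves
    pixels across the threshold symmetrically and the recovered fraction is
    unbiased.

    Returns (RGB uint8 image, stroma mask, true blue fraction).
    """
    if not 0.0 <= collagen_fraction <= 1.0:
        raise ValueError("collagen_fraction must be in [0, 1]")
    pink_conc = background_conc + 2.0 * (threshold - background_conc)
    rng = np.random.default_rng(seed)
    field_ = gaussian(rng.normal(size=shape), sigma=smooth_sigma, preserve_range=True)
    order = field_.ravel().argsort().argsort()
    u = (order + 0.5) / order.size  # exact uniform ranks
    pink_mask = (u > collagen_fraction).reshape(shape)
    c_pink = np.where(pink_mask, pink_conc, background_conc)
    c_blue = np.where(pink_mask, background_conc, blue_conc)
    basis = StainBasis.from_vectors(*stain_vectors)
    od = (
        c_blue[..., None] * basis.v_blue[None, None, :]
        + c_pink[..., None] * basis.v_pink[None, None, :]
    )
    rgb = od_to_rgb(od)
    stroma = MaskRaster(mask=np.ones(shape, bool), pixel_size=pixel_size)
    return rgb, stroma, float(collagen_fraction)


# ---------------------------------------------------------------------------
# methylation, bulk, survival
# ---------------------------------------------------------------------------

def simulate_methylation(
    expression_per_sample: pd.Series,
    n_promoter_sites: int = 12,
    n_body_sites: int = 6,
    slope: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.3,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Promoter betas anti-correlated with expression; body betas independent.

    promoter beta = logistic(a_site - slope * z + eps), body beta =
    logistic(a_site + eps), with z the standardized log-expression.
    """
    rng = np.random.default_rng(seed)
    expr = expression_per_sample.astype(float)
    z = (expr - expr.mean()) / max(expr.std(ddof=0), 1e-12)
    sites, regions, rows = [], [], []
    prom_labels = ["TSS1500", "TSS200", "5'UTR", "1stExon"]
    body_labels = ["Body", "3'UTR"]
    for i in range(n_promoter_sites):
        a = rng.normal(0.0, 0.3)
        eps = rng.normal(0.0, noise_sd, size=len(expr))
        rows.append(expit(a - slope * z.to_numpy() + eps))
        sites.append(f"cg_prom_{i:02d}")
        regions.append(prom_labels[i % len(prom_labels)])
    for i in range(n_body_sites):
        a = rng.normal(0.0, 0.3)
        eps = rng.normal(0.0, noise_sd, size=len(expr))
        rows.append(expit(a + eps))
        sites.append(f"cg_body_{i:02d}")
        regions.append(body_labels[i % len(body_labels)])
    betas = pd.DataFrame(rows, index=sites, columns=expr.index)
    return betas, pd.Series(regions, index=sites, name="region"), {"slope": slope}


def simulate_bulk(
    patients: int = 37,
    samples_per_patient: int = 5,
    effects: Mapping[str, float] | None = None,
    sigma_u2: float = 0.5,
    sigma_e2: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Patient-clustered bulk expression of one gene.

    y = intercept + cancer/grade/relapse/stroma/age effects + u_patient + eps.
    Cancer status and grade vary per sample; relapse and age are patient
    level.  Truth records every beta and both variance components.
    """
    rng = np.random.default_rng(seed)
    eff = {
        "intercept": 5.0,
        "cancer": 1.5,
        "HG": 0.5,
        "relapse": 0.8,
        "stroma_36-64%": 0.3,
        "stroma_>=65%": 0.6,
        "age_59-64": 0.0,
        "age_65-73": 0.0,
    }
    if effects:
        eff.update(effects)
    rows = []
    for pi in range(patients):
        pid = f"P{pi:02d}"
        u = rng.normal(0.0, np.sqrt(sigma_u2))
        age = AGE_CATEGORIES_local[rng.integers(0, 3)]
        relapse = "relapse" if rng.random() < 0.55 else "relapse-free"
        for si in range(samples_per_patient):
            cancer = "cancer" if rng.random() < 0.65 else "non-cancer"
            grade = ("HG" if rng.random() < 0.45 else "LG") if cancer == "cancer" else ""
            stroma = STROMA_CATEGORIES_local[rng.integers(0, 3)]
            y = eff["intercept"] + u + rng.normal(0.0, np.sqrt(sigma_e2))
            if cancer == "cancer":
                y += eff["cancer"]
                if grade == "HG":
                    y += eff["HG"]
            if relapse == "relapse":
                y += eff["relapse"]
            if stroma != "<=35%":
                y += eff[f"stroma_{stroma}"]
            if age != "51-58":
                y += eff[f"age_{age}"]
            rows.append(
                {
                    "sample_id": f"{pid}_{si}",
                    "patient_id": pid,
                    "expression": y,
                    "cancer_status": cancer,
                    "grade": grade,
                    "relapse_status": relapse,
                    "stroma_category": stroma,
                    "age_category": age,
                }
            )
    table = pd.DataFrame(rows)
    # marginal contrasts as estimated by a model adjusting only for stroma
    # and age: grade mixes into the cancer effect at its sampling rate
    marginal = {
        "non-cancer vs cancer": eff["cancer"] + 0.45 * eff["HG"],
        "relapse-free vs relapse": eff["relapse"],
        "LG vs HG": eff["HG"],
        "relapse-free cancer vs relapse cancer": eff["relapse"],
    }
    truth = {
        "effects": dict(eff),
        "marginal": marginal,
        "sigma_u2": sigma_u2,
        "sigma_e2": sigma_e2,
    }
    return table, truth


STROMA_CATEGORIES_local = ("<=35%", "36-64%", ">=65%")
AGE_CATEGORIES_local = ("51-58", "59-64", "65-73")


def simulate_survival(
    expression: pd.Series,
    gamma: float = 1.0,
    base_rate: float = 0.2,
    censor_horizon: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Exponential relapse times with rate base_rate * exp(gamma * z).

    z is the standardized expression; times past the horizon are censored at
    the horizon.
    """
    rng = np.random.default_rng(seed)
    expr = expression.astype(float)
    z = (expr - expr.mean()) / max(expr.std(ddof=0), 1e-12)
    rate = base_rate * np.exp(gamma * z.to_numpy())
    t = rng.exponential(1.0 / rate)
    event = t <= censor_horizon
    t = np.minimum(t, censor_horizon)
    out = pd.DataFrame(
        {
            "patient_id": expr.index,
            "expression": expr.to_numpy(),
            "time": t,
            "event": event.astype(int),
        }
    )
    return out, {"gamma": gamma, "base_rate": base_rate, "horizon": censor_horizon}


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def simulate_study(
    cfg: PipelineConfig | None = None,
    seed: int | None = None,
    n_samples: int = 8,
    n_genes: int = 300,
    tissue_um: float = 2600.0,
    pixel_size: float = 5.0,
    mean_cells: float = 21.0,
    marker_log2fc: float = 3.0,
    coupling_sd: float = 0.35,
    trichrome_px: int = 256,
    methyl_slope: float = 1.0,
    survival_gamma: float = 1.0,
    dispersion: float = 0.3,
) -> SimulatedStudy:
    """Generate a complete multi-sample study with consistent identifiers.

    Samples alternate normal / LG / HG histology; a per-sample latent factor
    couples stroma-marker expression, partner-gene expression and collagen
    content, providing the planted structure that the correlation and stain
    stages are expected to recover.
    """
    cfg = cfg or PipelineConfig()
    seed = cfg.seed if seed is None else int(seed)
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(6 + 4 * n_samples)
    sig_seed = seeds[0].generate_state(1)[0] % (2**31)

    signatures, markers = make_signatures(
        n_genes=n_genes, seed=int(sig_seed), marker_log2fc=marker_log2fc
    )
    rng = np.random.default_rng(seeds[1].generate_state(2))
    disp = pd.Series(
        rng.uniform(0.1, dispersion * 2 - 0.1, size=signatures.shape[1]),
        index=signatures.columns,
        name="dispersion",
    )

    kinds = ["normal", "LG", "HG"] * ((n_samples + 2) // 3)
    sample_ids = [f"S{si:02d}" for si in range(n_samples)]
    latent = rng.normal(0.0, coupling_sd, size=n_samples)

    spots, masks, counts, ccs, fracs_tables = {}, {}, {}, {}, {}
    shape = (int(tissue_um / pixel_size), int(tissue_um / pixel_size))
    coupled = [g for g in signatures.columns if g.startswith(("STROMARK", "ECMPART"))]
    tissue_truth = None
    for si, sid in enumerate(sample_ids):
        kind = kinds[si]
        if kind == "normal":
            classes = ["stroma", "non-cancer gland", "lumen"]
            props = [0.55, 0.35, 0.10]
        elif kind == "LG":
            classes = ["stroma", "non-cancer gland", "GG1", "GG2", "lumen"]
            props = [0.45, 0.20, 0.15, 0.10, 0.10]
        else:
            classes = ["stroma", "non-cancer gland", "GG3", "GG4", "lumen"]
            props = [0.45, 0.15, 0.18, 0.12, 0.10]
        mseed = seeds[6 + 4 * si].generate_state(1)[0] % (2**31)
        m = make_tissue_masks(shape, classes, int(mseed), props, pixel_size=pixel_size)
        # per-sample latent factor scales the coupled genes
        sig_s = signatures.copy()
        sig_s[coupled] = sig_s[coupled] * 2.0 ** latent[si]
        truth_s = TissueTruth(
            class_rasters=m,
            cell_type_signatures=sig_s,
            class_compositions={c: np.array(DEFAULT_COMPOSITIONS[c]) for c in classes},
            marker_genes=markers,
            dispersion=disp,
            pixel_size=pixel_size,
        )
        if tissue_truth is None:
            tissue_truth = truth_s
        grid = make_spot_grid(
            tissue_um - pixel_size, tissue_um - pixel_size, cfg.spot_spacing, cfg.spot_diameter
        )
        grid = [
            SpotGeometry(f"{sid}_{s.spot_id}", s.center_x, s.center_y, s.diameter, s.row, s.col)
            for s in grid
        ]
        cseed = seeds[6 + 4 * si + 1].generate_state(1)[0] % (2**31)
        cnt, cc, dom = simulate_counts(grid, truth_s, int(cseed), mean_cells=mean_cells)
        spots[sid] = grid
        masks[sid] = m
        counts[sid] = cnt
        ccs[sid] = cc
        fracs_tables[sid] = dom

    # trichrome coupled to the latent factor: more marker -> more collagen
    trichrome, stroma_masks, collagen_truth = {}, {}, {}
    for si, sid in enumerate(sample_ids):
        cf = float(np.clip(0.5 + 0.45 * np.tanh(latent[si] / coupling_sd * 0.9), 0.05, 0.95))
        tseed = seeds[6 + 4 * si + 2].generate_state(1)[0] % (2**31)
        img, smask, true_cf = simulate_trichrome(
            (trichrome_px, trichrome_px), cf, int(tseed), pixel_size=cfg.stain_resolution
        )
        trichrome[sid] = img
        stroma_masks[sid] = smask
        collagen_truth[sid] = true_cf

    # per-spot cell-type fraction tables (as an external deconvolution would supply)
    celltype_fractions = {}
    frng = np.random.default_rng(seeds[2].generate_state(2))
    for sid in sample_ids:
        dom = fracs_tables[sid]
        rows = []
        for cls in dom:
            alpha = np.asarray(DEFAULT_COMPOSITIONS[cls], float)
            rows.append(frng.dirichlet(alpha))
        celltype_fractions[sid] = pd.DataFrame(
            rows, index=dom.index, columns=list(CELL_TYPES)
        )

    bseed = seeds[3].generate_state(1)[0] % (2**31)
    bulk, bulk_truth = simulate_bulk(seed=int(bseed))
    mseed = seeds[4].generate_state(1)[0] % (2**31)
    betas, regions, methyl_truth = simulate_methylation(
        bulk.set_index("sample_id")["expression"].iloc[:64],
        slope=methyl_slope,
        seed=int(mseed),
    )
    from .bulk import representative_sample

    rep = representative_sample(bulk)
    sseed = seeds[5].generate_state(1)[0] % (2**31)
    surv, surv_truth = simulate_survival(
        rep.set_index("patient_id")["expression"],
        gamma=survival_gamma,
        seed=int(sseed),
    )

    truth = {
        "seed": seed,
        "marker_genes": markers,
        "marker_log2fc": marker_log2fc,
        "latent": {s: float(l) for s, l in zip(sample_ids, latent)},
        "collagen": collagen_truth,
        "bulk": bulk_truth,
        "methylation": methyl_truth,
        "survival": surv_truth,
        "sample_kinds": dict(zip(sample_ids, kinds)),
        "true_spot_class": {s: fracs_tables[s].to_dict() for s in sample_ids},
        "mean_cells": mean_cells,
    }
    return SimulatedStudy(
        cfg=cfg,
        seed=seed,
        samples=sample_ids,
        spots=spots,
        masks=masks,
        counts=counts,
        cell_counts=ccs,
        trichrome=trichrome,
        stroma_masks=stroma_masks,
        collagen_truth=collagen_truth,
        celltype_fractions=celltype_fractions,
        bulk=bulk,
        methylation_betas=betas,
        methylation_regions=regions,
        survival=surv,
        truth=truth,
        tissue_truth=tissue_truth,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write a study to disk in exactly the formats the readers consume."""
    outdir = Path(outdir)
    for sid in study.samples:
        d = outdir / sid
        d.mkdir(parents=True, exist_ok=True)
        spio.write_count_matrix(
            study.counts[sid], d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv"
        )
        ps = next(iter(study.masks[sid].values())).pixel_size
        spio.write_positions(study.spots[sid], d / "tissue_positions.csv", pixel_size=ps)
        spio.write_cell_counts(study.cell_counts[sid], d / "cell_counts.csv")
        mdir = d / "masks"
        mdir.mkdir(exist_ok=True)
        for cls, m in study.masks[sid].items():
            safe = cls.replace(" ", "_")
            spio.write_mask(m.mask, mdir / f"{safe}.png")
        spio.write_rgb_image(study.trichrome[sid], d / "trichrome.png")
        spio.write_mask(study.stroma_masks[sid].mask, d / "stroma_mask.png")
        study.celltype_fractions[sid].rename_axis("spot_id").to_csv(
            d / "celltype_fractions.csv"
        )
    spio.write_table(study.bulk, outdir / "bulk_expression.csv")
    spio.write_methylation(
        study.methylation_betas,
        study.methylation_regions,
        outdir / "methylation_betas.csv",
        outdir / "methylation_regions.csv",
    )
    spio.write_table(study.survival, outdir / "survival.csv")
    meta = {
        "samples": study.samples,
        "pixel_size": next(iter(study.masks[study.samples[0]].values())).pixel_size,
        "stain_pixel_size": study.stroma_masks[study.samples[0]].pixel_size,
        "seed": study.seed,
        "truth": study.truth,
    }
    with open(outdir / "study.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
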