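"""Synthetic multi-organ single-cell datasets with planted ground truth.

Three generators emulate the statistical structure of a multi-donor,
multi-organ developmental immune atlas:

* :func:`generate_cell_dataset` — cell tables with a low-dimensional
  embedding drawn from per-cell-type Gaussians, negative-binomial gene
  counts with planted marker genes, sample composition following
  log-linear gestational-age trends, and optional CD45 FACS enrichment.
* :func:`generate_repertoire` — paired-chain style AIRR rearrangement
  tables with group-biased V/J segment usage, junction-length shifts,
  non-templated (NP) insertion lengths and somatic mutation loads, plus a
  per-cell table carrying a planted cycling indicator.
* :func:`generate_spatial_abundance` — spot × cell-type abundance matrices
  built from spatially compact low-rank microenvironment factors plus
  nonnegative noise.

Every generator records the planted truth (slopes, marker genes, odds
ratios, factor loadings, sorted-fraction proportions) so downstream
recovery can be scored without re-reading the configuration.  All
randomness flows from ``SimConfig.seed``; a fixed seed reproduces output
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "SimConfig",
    "RepertoireSpec",
    "SpatialSpec",
    "PlantedMarkers",
    "generate_cell_dataset",
    "generate_repertoire",
    "generate_spatial_abundance",
    "generate_pseudobulk_dataset",
]

IMMUNE_PREFIX = "immune"
NONIMMUNE_PREFIX = "stromal"

_NT = np.array(list("ACGT"))


@dataclass
class PlantedMarkers:
    """A block of planted differentially expressed genes.

    ``condition`` selects which cells carry the raised mean:
    ``"always"`` (constitutive type marker), ``"late"`` (a stage-specific
    cell state arising above the late-stage age threshold), or an organ
    code (organ-restricted marker).  ``log_fc`` is the natural-log fold
    change applied to the NB mean.  For the ``"late"`` condition only a
    ``state_fraction`` of the type's cells in late samples adopt the
    state, and state cells are displaced by ``embedding_shift`` latent
    units along a fixed random direction — stage-specific transcriptional
    states occupy their own region of the latent space, which is what
    lets neighborhood-level differential abundance localize them.
    """

    celltype: int
    n_genes: int
    log_fc: float
    condition: str = "late"
    base_mean: float = 0.3
    state_fraction: float = 0.5
    embedding_shift: float = 3.0


@dataclass
class RepertoireSpec:
    groups: tuple[str, ...] = ("B1", "matureB")
    cells_per_group: int = 2000
    n_v_segments: int = 12
    n_j_segments: int = 6
    # base V-segment usage: None draws a Dirichlet profile; "uniform" fixes
    # every segment at 1/n_v (controlled-DGP simulation studies)
    v_base: str | None = None
    # odds multipliers for segment usage, keyed (group, segment_name)
    usage_odds: dict = field(default_factory=dict)
    junction_mean: dict = field(default_factory=dict)  # group -> mean nt
    junction_sd: float = 6.0
    np_mean: dict = field(default_factory=dict)  # group -> Poisson mean nt
    mutation_rate: dict = field(default_factory=dict)  # group -> per-site rate
    cycling_prob: dict = field(default_factory=dict)  # group -> P(cycling)
    germline_length: int = 240
    d_quality_prob: float = 0.7
    n_donors: int = 4
    n_organs: int = 3


@dataclass
class SpatialSpec:
    n_factors: int = 10
    n_celltypes: int = 25
    grid_size: int = 30
    n_slides: int = 2
    noise_scale: float = 0.10  # noise SD as a fraction of mean signal
    member_types_per_factor: int = 2
    background_loading: float = 0.01
    bump_sigma_frac: float = 0.12  # bump SD as a fraction of grid size


@dataclass
class SimConfig:
    """Configuration for the cell-table generator.

    The defaults describe a mid-gestation multi-organ design: several
    donors spanning the 6–18 pcw window, a handful of organs, well
    separated cell types in a 10-dimensional latent embedding and
    negative-binomial counts with shared dispersion.
    """

    seed: int = 0
    n_donors: int = 6
    n_organs: int = 2
    n_celltypes: int = 5
    n_genes: int = 2000
    age_range: tuple[float, float] = (6.0, 18.0)
    cells_per_sample: int = 1500
    embedding_dim: int = 10
    center_scale: float = 6.0
    center_spread: float = 1.0
    # (n_celltypes, n_organs) log-linear age slopes per pcw; None = no trend
    abundance_trends: np.ndarray | None = None
    # (n_celltypes, n_organs) log-enrichment added to composition logits
    organ_enrichment: np.ndarray | None = None
    markers: tuple[PlantedMarkers, ...] = ()
    late_age_threshold: float = 12.0
    nb_dispersion: float = 0.3
    mean_depth: float = 5000.0
    # FACS: fraction of dissociations split into CD45+/- sorted samples
    sorted_fraction: float = 0.0
    sort_purity: float = 0.98
    n_immune_celltypes: int | None = None  # default: all but one
    repertoire: RepertoireSpec = field(default_factory=RepertoireSpec)
    spatial: SpatialSpec = field(default_factory=SpatialSpec)

    def validate(self) -> None:
        if self.n_celltypes < 2:
            raise ValueError("need at least 2 cell types")
        if self.cells_per_sample <= 0:
            raise ValueError("cells_per_sample must be positive")
        if self.age_range[0] <= 0:
            raise ValueError("ages are post-conception weeks and must be > 0")
        if self.center_scale > 0 and self.center_spread < 0:
            raise ValueError("negative spread")


def _celltype_names(cfg: SimConfig) -> list[str]:
    n_imm = cfg.n_immune_celltypes
    if n_imm is None:
        n_imm = max(cfg.n_celltypes - 1, 1)
    names = [f"{IMMUNE_PREFIX}_{i}" for i in range(n_imm)]
    names += [f"{NONIMMUNE_PREFIX}_{i}" for i in range(cfg.n_celltypes - n_imm)]
    return names


def _type_centers(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    centers = rng.normal(scale=cfg.center_scale, size=(cfg.n_celltypes, cfg.embedding_dim))
    if cfg.center_scale > 0:
        # reject degenerate (coincident) centers when separation is requested
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-6:
            raise ValueError("degenerate cell-type centers; increase center_scale")
    return centers


def _gene_means(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Per-celltype NB mean matrix (n_celltypes, n_genes) plus marker truth."""
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    marker_truth = []
    # reserve the leading genes for planted markers so blocks never collide
    cursor = 0
    for spec in cfg.markers:
        idx = np.arange(cursor, cursor + spec.n_genes)
        cursor += spec.n_genes
        base[idx] = spec.base_mean
        marker_truth.append(
            {
                "genes": idx,
                "celltype": spec.celltype,
                "log_fc": spec.log_fc,
                "condition": spec.condition,
                "state_fraction": spec.state_fraction,
                "embedding_shift": spec.embedding_shift,
            }
        )
    base *= cfg.mean_depth / base.sum()
    means = np.tile(base, (cfg.n_celltypes, 1))
    # mild constitutive type structure on non-marker genes
    if cfg.n_genes > cursor:
        wobble = rng.lognormal(mean=0.0, sigma=0.15, size=(cfg.n_celltypes, cfg.n_genes - cursor))
        means[:, cursor:] *= wobble
    return means, {"blocks": marker_truth, "reserved": cursor}


def _sample_nb(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def generate_cell_dataset(config: SimConfig) -> ad.AnnData:
    """Simulate a multi-sample cell table as :class:`anndata.AnnData`.

    Returns an AnnData with raw NB counts in ``X`` (sparse), the latent
    embedding in ``obsm["X_emb"]``, per-cell metadata in ``obs`` and the
    planted ground truth in ``uns["ground_truth"]``.  With
    ``config.n_genes == 0`` the expression matrix is empty, which is
    sufficient (and much faster) for abundance-only analyses.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    types = _celltype_names(config)
    organs = [f"OR{j}" for j in range(config.n_organs)]
    centers = _type_centers(config, rng)

    slopes = config.abundance_trends
    if slopes is None:
        slopes = np.zeros((config.n_celltypes, config.n_organs))
    slopes = np.asarray(slopes, dtype=float)
    enrich = config.organ_enrichment
    if enrich is None:
        enrich = np.zeros((config.n_celltypes, config.n_organs))
    enrich = np.asarray(enrich, dtype=float)
    # fixed displacement directions for late-state marker blocks
    state_dirs = rng.normal(size=(max(len(config.markers), 1), config.embedding_dim))
    state_dirs /= np.linalg.norm(state_dirs, axis=1, keepdims=True)

    base_prop = rng.dirichlet(np.full(config.n_celltypes, 8.0))
    lo, hi = config.age_range
    donor_ages = np.linspace(lo + 0.3, hi - 0.3, config.n_donors)
    donor_ages = donor_ages + rng.uniform(-0.25, 0.25, size=config.n_donors)
    age_mid = 0.5 * (lo + hi)

    n_imm = config.n_immune_celltypes
    if n_imm is None:
        n_imm = max(config.n_celltypes - 1, 1)
    immune_mask = np.zeros(config.n_celltypes, dtype=bool)
    immune_mask[:n_imm] = True

    if config.n_genes > 0:
        means, marker_truth = _gene_means(config, rng)
    else:
        means, marker_truth = None, {"blocks": [], "reserved": 0}

    sorted_dissociations = set()
    if config.sorted_fraction > 0:
        n_sorted = int(round(config.sorted_fraction * config.n_donors * config.n_organs))
        all_pairs = [(d, o) for d in range(config.n_donors) for o in range(config.n_organs)]
        pick = rng.choice(len(all_pairs), size=n_sorted, replace=False)
        sorted_dissociations = {all_pairs[i] for i in pick}

    obs_frames: list[pd.DataFrame] = []
    emb_blocks: list[np.ndarray] = []
    sort_truth: dict[str, float] = {}

    # pre-draw sample sizes so the count matrix can be allocated once
    pairs = [(d, o) for d in range(config.n_donors) for o in range(config.n_organs)]
    sizes = rng.poisson(config.cells_per_sample, size=len(pairs))
    total_cells = int(sizes.sum())
    X_full = (
        np.empty((total_cells, config.n_genes), dtype=np.int32) if means is not None else None
    )
    row0 = 0

    for (d, o), n_cells in zip(pairs, sizes):
        age = float(donor_ages[d])
        if n_cells == 0:
            continue
        logits = np.log(base_prop) + slopes[:, o] * (age - age_mid) + enrich[:, o]
        prop = np.exp(logits - logits.max())
        prop /= prop.sum()
        cell_types = rng.choice(config.n_celltypes, size=n_cells, p=prop)

        if (d, o) in sorted_dissociations:
            is_imm = immune_mask[cell_types]
            goes_pos = np.where(
                is_imm,
                rng.random(n_cells) < config.sort_purity,
                rng.random(n_cells) >= config.sort_purity,
            )
            fractions = np.where(goes_pos, "CD45pos", "CD45neg")
            pi_pos = float(goes_pos.mean())
            sort_truth[f"D{d}_{organs[o]}_CD45pos"] = pi_pos
            sort_truth[f"D{d}_{organs[o]}_CD45neg"] = 1.0 - pi_pos
        else:
            fractions = np.full(n_cells, "unsorted")

        emb = centers[cell_types] + rng.normal(
            scale=config.center_spread, size=(n_cells, config.embedding_dim)
        )

        # which cells carry each planted marker block
        active_masks = []
        late_state = np.zeros(n_cells, dtype=bool)
        for bi, blk in enumerate(marker_truth["blocks"]):
            in_type = cell_types == blk["celltype"]
            if blk["condition"] == "always":
                active = in_type
            elif blk["condition"] == "late":
                active = (
                    in_type
                    & (age > config.late_age_threshold)
                    & (rng.random(n_cells) < blk["state_fraction"])
                )
                emb[active] += blk["embedding_shift"] * state_dirs[bi]
                late_state |= active
            else:  # organ-restricted
                active = in_type & (organs[o] == blk["condition"])
            active_masks.append(active)
        emb_blocks.append(emb)

        if means is not None:
            mu = means[cell_types]  # fancy indexing copies
            for blk, active in zip(marker_truth["blocks"], active_masks):
                if np.any(active):
                    mu[np.ix_(active, blk["genes"])] *= np.exp(blk["log_fc"])
            X_full[row0 : row0 + n_cells] = _sample_nb(rng, mu, config.nb_dispersion)
            row0 += n_cells

        sample_base = f"D{d}_{organs[o]}"
        sample_ids = np.where(
            fractions == "unsorted", sample_base, np.char.add(f"{sample_base}_", fractions)
        )
        obs_frames.append(
            pd.DataFrame(
                {
                    "donor_id": f"D{d}",
                    "organ": organs[o],
                    "age_pcw": age,
                    "sort_fraction": fractions,
                    "celltype_label": np.asarray(types, dtype=object)[cell_types],
                    "sample_id": sample_ids,
                    "late_state": late_state,
                }
            )
        )

    if not obs_frames:
        raise ValueError("zero cells generated")

    obs = pd.concat(obs_frames, ignore_index=True)
    obs.index = pd.Index([f"cell_{i}" for i in range(len(obs))])
    emb = np.vstack(emb_blocks)
    if X_full is not None:
        X = X_full[: len(obs)]  # counts are dense: droplet tables at this
        # gene-panel size are too dense for sparse storage to pay off
        var = pd.DataFrame(index=[f"gene_{g}" for g in range(config.n_genes)])
    else:
        X = sparse.csr_matrix((len(obs), 0))
        var = pd.DataFrame(index=pd.Index([], dtype=object))

    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.obsm["X_emb"] = emb
    adata.uns["ground_truth"] = {
        "abundance_slopes": slopes,
        "celltype_names": types,
        "immune_mask": immune_mask,
        "marker_blocks": [
            {
                "genes": [f"gene_{g}" for g in blk["genes"]],
                "celltype": types[blk["celltype"]],
                "log_fc": blk["log_fc"],
                "condition": blk["condition"],
            }
            for blk in marker_truth["blocks"]
        ],
        "sort_proportions": sort_truth,
        "late_age_threshold": config.late_age_threshold,
        "type_centers": centers,
    }
    return adata


# ---------------------------------------------------------------------------
# immune repertoires
# ---------------------------------------------------------------------------

def _segment_probs(n: int, rng: np.random.Generator) -> np.ndarray:
    w = rng.dirichlet(np.full(n, 5.0))
    return w


def generate_repertoire(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an AIRR-style chain table plus a per-cell metadata table.

    Returns ``(cells, chains)``.  ``chains`` follows the AIRR Rearrangement
    column naming (cell_id, locus, v_call, d_call, j_call, junction,
    junction_length, np1_length, np2_length, productive) extended with
    ``mutation_frequency``, ``d_quality``, ``sequence_alignment`` and
    ``germline_alignment``.  ``cells`` carries group/donor/organ and a
    planted cycling marker count (``MKI67_count``).  Planted effects are
    attached to ``chains.attrs["ground_truth"]``.
    """
    spec = config.repertoire
    if len(spec.groups) < 2:
        raise ValueError("repertoire_spec must define at least 2 groups")
    for g, r in spec.mutation_rate.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"mutation rate for {g} outside [0, 1]")
    for key, odds in spec.usage_odds.items():
        if odds <= 0:
            raise ValueError(f"usage odds for {key} must be > 0")

    rng = np.random.default_rng(config.seed + 7)
    v_names = [f"IGHV{i + 1}" for i in range(spec.n_v_segments)]
    j_names = [f"IGHJ{i + 1}" for i in range(spec.n_j_segments)]
    if spec.v_base == "uniform":
        base_v = np.full(spec.n_v_segments, 1.0 / spec.n_v_segments)
    else:
        base_v = _segment_probs(spec.n_v_segments, rng)
    base_j = _segment_probs(spec.n_j_segments, rng)

    germline = "".join(rng.choice(_NT, size=spec.germline_length))

    cell_rows, chain_rows = [], []
    cid = 0
    for group in spec.groups:
        jl_mean = spec.junction_mean.get(group, 45.0)
        np_mean = spec.np_mean.get(group, 4.0)
        mut_rate = spec.mutation_rate.get(group, 0.0)
        cyc_p = spec.cycling_prob.get(group, 0.15)

        v_odds = np.array([spec.usage_odds.get((group, v), 1.0) for v in v_names])
        v_p = base_v * v_odds
        v_p /= v_p.sum()

        for _ in range(spec.cells_per_group):
            donor = f"D{rng.integers(spec.n_donors)}"
            organ = f"OR{rng.integers(spec.n_organs)}"
            cycling = rng.random() < cyc_p
            mki67 = int(1 + rng.poisson(2.0)) if cycling else 0
            cell_id = f"rcell_{cid}"
            cid += 1
            cell_rows.append(
                {
                    "cell_id": cell_id,
                    "group": group,
                    "donor": donor,
                    "organ": organ,
                    "MKI67_count": mki67,
                }
            )
            jl = max(9, int(round(rng.normal(jl_mean, spec.junction_sd))))
            np1 = int(rng.poisson(np_mean))
            np2 = int(rng.poisson(np_mean))
            n_mut = rng.binomial(spec.germline_length, mut_rate)
            seq = np.array(list(germline))
            if n_mut:
                pos = rng.choice(spec.germline_length, size=n_mut, replace=False)
                for pmut in pos:
                    choices = [b for b in "ACGT" if b != seq[pmut]]
                    seq[pmut] = choices[rng.integers(3)]
            chain_rows.append(
                {
                    "cell_id": cell_id,
                    "locus": "IGH",
                    "v_call": rng.choice(v_names, p=v_p),
                    "d_call": f"IGHD{rng.integers(4) + 1}",
                    "j_call": rng.choice(j_names, p=base_j),
                    "junction": "".join(rng.choice(_NT, size=jl)),
                    "junction_length": jl,
                    "np1_length": np1,
                    "np2_length": np2,
                    "productive": "T",
                    "mutation_frequency": n_mut / spec.germline_length,
                    "d_quality": bool(rng.random() < spec.d_quality_prob),
                    "sequence_alignment": "".join(seq),
                    "germline_alignment": germline,
                }
            )

    cells = pd.DataFrame(cell_rows)
    chains = pd.DataFrame(chain_rows)
    chains.attrs["ground_truth"] = {
        "usage_odds": dict(spec.usage_odds),
        "junction_mean": dict(spec.junction_mean),
        "np_mean": dict(spec.np_mean),
        "mutation_rate": dict(spec.mutation_rate),
        "cycling_prob": dict(spec.cycling_prob),
        "base_v_probs": dict(zip(v_names, base_v)),
    }
    cells.attrs["ground_truth"] = chains.attrs["ground_truth"]
    return cells, chains


# ---------------------------------------------------------------------------
# spatial abundances
# ---------------------------------------------------------------------------

def generate_spatial_abundance(config: SimConfig) -> dict:
    """Simulate spot × cell-type abundances from compact low-rank factors.

    Each microenvironment factor is a Gaussian bump on a square spot grid
    (spot weights ``W``) loading on a small, mostly disjoint set of member
    cell types (``H``).  The observed matrix is ``W @ H`` plus nonnegative
    half-normal noise.

    Returns a dict with ``abundance`` (DataFrame, spots × cell types),
    ``coords`` (DataFrame with x, y, slide_id) and ``truth`` containing
    W, H, planted member sets and per-factor planted region masks.
    """
    spec = config.spatial
    if spec.n_factors <= 0 or spec.n_celltypes < spec.n_factors:
        raise ValueError("need at least as many cell types as factors")
    rng = np.random.default_rng(config.seed + 13)

    g = spec.grid_size
    xs, ys = np.meshgrid(np.arange(g), np.arange(g))
    grid = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    n_spots_slide = g * g

    types = [f"ct_{i}" for i in range(spec.n_celltypes)]
    # mostly disjoint member sets, round-robin over cell types
    H = np.full((spec.n_factors, spec.n_celltypes), spec.background_loading)
    member_sets = []
    perm = rng.permutation(spec.n_celltypes)
    cursor = 0
    for k in range(spec.n_factors):
        members = []
        for _ in range(spec.member_types_per_factor):
            members.append(int(perm[cursor % spec.n_celltypes]))
            cursor += 1
        for m in members:
            H[k, m] = rng.uniform(0.8, 1.2)
        member_sets.append(sorted(types[m] for m in members))

    sigma = spec.bump_sigma_frac * g
    W_blocks, coord_rows = [], []
    region_masks = []
    for s in range(spec.n_slides):
        slide = f"slide_{s}"
        # best-candidate sampling spreads bump centers apart: planted
        # microenvironments are identifiable only if their zones do not
        # coincide, as holds for real tissue compartments
        centers = np.empty((spec.n_factors, 2))
        centers[0] = rng.uniform(0.15 * g, 0.85 * g, size=2)
        for k in range(1, spec.n_factors):
            cands = rng.uniform(0.15 * g, 0.85 * g, size=(30, 2))
            d2 = ((cands[:, None, :] - centers[None, :k, :]) ** 2).sum(-1).min(axis=1)
            centers[k] = cands[np.argmax(d2)]
        d2 = ((grid[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        W = rng.uniform(0.8, 1.2, size=spec.n_factors) * np.exp(-d2 / (2 * sigma**2))
        W_blocks.append(W)
        region_masks.append(W > 0.1 * W.max(axis=0, keepdims=True).max())
        for i in range(n_spots_slide):
            coord_rows.append(
                {
                    "spot_id": f"{slide}_spot_{i}",
                    "x": grid[i, 0],
                    "y": grid[i, 1],
                    "slide_id": slide,
                }
            )

    W_all = np.vstack(W_blocks)
    signal = W_all @ H
    noise = np.abs(rng.normal(scale=spec.noise_scale * signal.mean(), size=signal.shape))
    abundance = signal + noise if spec.noise_scale > 0 else signal

    coords = pd.DataFrame(coord_rows).set_index("spot_id")
    abundance_df = pd.DataFrame(abundance, index=coords.index, columns=types)
    truth = {
        "W": W_all,
        "H": H,
        "member_sets": member_sets,
        "region_mask": np.vstack(region_masks),  # spots × factors, per planted bump
        "celltypes": types,
    }
    return {"abundance": abundance_df, "coords": coords, "truth": truth}


# ---------------------------------------------------------------------------
# direct pseudobulk simulation (for interaction-model testing)
# ---------------------------------------------------------------------------

def generate_pseudobulk_dataset(
    seed: int,
    n_donors: int = 6,
    n_organs: int = 3,
    n_celltypes: int = 3,
    n_genes: int = 200,
    dispersion: float = 0.1,
    base_mean: float = 50.0,
    library_scatter: float = 0.3,
    interaction_genes: int = 0,
    interaction_lfc: float = 1.0,
    technical_genes: int = 0,
    technical_lfc: float = 1.5,
    target_organ: str = "OR0",
    target_celltype: str = "immune_0",
    technical_celltypes: tuple[int, ...] = (0, 1, 2),
) -> dict:
    """Simulate pseudobulk counts directly from the interaction NB model.

    One pseudobulk per (donor, organ, cell type).  ``interaction_genes``
    get an organ×celltype effect of ``interaction_lfc`` only in the target
    pairing; ``technical_genes`` get an organ effect of ``technical_lfc``
    in every cell type listed in ``technical_celltypes`` (default: all —
    tissue-processing artifacts such as dissociation stress hit the whole
    sample, which is exactly what the control-cell-type filter catches).
    """
    rng = np.random.default_rng(seed)
    organs = [f"OR{i}" for i in range(n_organs)]
    celltypes = [f"immune_{i}" for i in range(n_celltypes)]
    meta_rows = []
    for d in range(n_donors):
        for o in organs:
            for c in celltypes:
                meta_rows.append({"donor": f"D{d}", "organ": o, "celltype": c})
    meta = pd.DataFrame(meta_rows)
    n_pb = len(meta)

    gene_mu = rng.lognormal(mean=np.log(base_mean), sigma=0.8, size=n_genes)
    lib = np.exp(rng.normal(scale=library_scatter, size=n_pb))
    donor_eff = rng.normal(scale=0.1, size=n_donors)

    mu = np.outer(gene_mu, lib)
    for p in range(n_pb):
        mu[:, p] *= np.exp(donor_eff[int(meta.loc[p, "donor"][1:])])

    inter_idx = np.arange(interaction_genes)
    tech_idx = np.arange(interaction_genes, interaction_genes + technical_genes)
    is_target = (meta["organ"] == target_organ) & (meta["celltype"] == target_celltype)
    mu[np.ix_(inter_idx, np.where(is_target)[0])] *= np.exp(interaction_lfc)
    tech_types = [celltypes[i] for i in technical_celltypes]
    is_tech = (meta["organ"] == target_organ) & meta["celltype"].isin(tech_types)
    mu[np.ix_(tech_idx, np.where(is_tech)[0])] *= np.exp(technical_lfc)

    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
    counts = rng.poisson(lam)
    meta["library_size"] = counts.sum(axis=0)
    meta["n_cells"] = 100
    genes = [f"gene_{i}" for i in range(n_genes)]
    return {
        "counts": pd.DataFrame(counts, index=genes, columns=meta.index),
        "meta": meta,
        "truth": {
            "interaction_genes": [genes[i] for i in inter_idx],
            "technical_genes": [genes[i] for i in tech_idx],
            "interaction_lfc": interaction_lfc,
            "technical_lfc": technical_lfc,
            "target_organ": target_organ,
            "target_celltype": target_celltype,
        },
    }
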