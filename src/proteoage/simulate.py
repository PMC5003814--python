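"""Synthetic triple-SILAC aging-proteome data with known ground truth.

Emulates the statistical structure of a three-age-point SILAC experiment in
*C. elegans* (heavy = day 1, medium = day 5, light = day 10 of adulthood):

* log-normal protein abundances spanning roughly seven orders of magnitude;
* log2-ratio measurement error whose SD grows as intensity falls (linearly
  in log10 intensity, down to a floor);
* a minority of proteins with planted age trends drawn from six trend
  archetypes (sign patterns over the day5/day1 and day10/day5 intervals);
* independent per-cell missingness;
* four-compartment fractionation profiles (cytoplasm, membrane, nucleus,
  cytoskeleton/insoluble);
* strain-specific mutant-vs-wild-type scaling behaviour for age-variant
  proteins (younger / unchanged / older patterns);
* fluorescence-reporter z-stacks with diffuse cytoplasmic signal plus
  punctate foci.

Every generator records its ground truth so downstream statistics can be
scored against what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PAIRS = ("MH", "LM", "LH")

#: Trend archetypes as sign patterns over the (M/H, L/M) intervals.
#: Archetype 3 is the sharp up-then-down shape; 6 is its mirror image.
ARCHETYPE_SIGNS = {
    1: (1, 1),
    2: (1, 0),
    3: (1, -1),
    4: (-1, -1),
    5: (-1, 0),
    6: (-1, 1),
}

SCALING_CALLS = ("younger", "unchanged", "older")

#: Default planted (younger, unchanged, older) proportions per strain for
#: age-variant proteins, mirroring reported long-/short-lived mutant cohorts.
DEFAULT_STRAINS: dict[str, tuple[float, float, float]] = {
    "daf-2": (0.35, 0.40, 0.25),
    "hsf-1": (0.02, 0.36, 0.62),
}

COMPARTMENTS = ("cytoplasm", "membrane", "nucleus", "cytoskeleton")


@dataclass
class SimulationParams:
    """Study-condition knobs for :func:`simulate_proteome`.

    Defaults describe a deep adult-worm SILAC dataset: ~7 decades of
    intensity dynamic range (1st-99.9th percentile of a log10-normal with
    SD 1.3 spans ~7), ~8% age-variant proteins, and ratio noise falling
    from ~0.3 (faint proteins) to 0.05 (bright) in log2 units.
    """

    n_proteins: int = 5000
    n_replicates: int = 3
    abundance_log10_mean: float = 7.0
    abundance_log10_sd: float = 1.3
    noise_sd_floor: float = 0.05
    noise_sd_slope: float = 0.05
    noise_cap_log10: float = 9.0
    frac_age_variant: float = 0.08
    effect_size_log2: float = 1.0
    archetype_weights: tuple[float, ...] = (1 / 6,) * 6
    missing_rate: float = 0.05
    decoy_rate: float = 0.01
    strains: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STRAINS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        if not 0 <= self.frac_age_variant <= 1:
            raise ValueError("frac_age_variant must lie in [0, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.effect_size_log2 <= 0:
            raise ValueError("effect_size_log2 must be positive")
        if self.noise_sd_floor < 0 or self.noise_sd_slope < 0:
            raise ValueError("noise SD parameters must be nonnegative")
        if self.noise_sd_floor == 0:
            raise ValueError("noise_sd_floor must be strictly positive")
        w = np.asarray(self.archetype_weights, dtype=float)
        if w.size != 6 or (w < 0).any():
            raise ValueError("archetype_weights must be 6 nonnegative reals")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("archetype_weights must sum to 1")
        for strain, props in self.strains.items():
            p = np.asarray(props, dtype=float)
            if p.size != 3 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"strain {strain!r}: proportions must be 3 nonnegative "
                    "reals summing to 1"
                )

    def noise_sd(self, log10_intensity: np.ndarray) -> np.ndarray:
        """SD of the log2-ratio error at a given log10 intensity."""
        x = np.asarray(log10_intensity, dtype=float)
        return self.noise_sd_floor + self.noise_sd_slope * np.maximum(
            0.0, self.noise_cap_log10 - x
        )


@dataclass
class SyntheticTruth:
    """Ground truth recorded by :func:`simulate_proteome`.

    ``proteins`` is indexed by protein id and carries the planted trend
    (``true_log2_MH/LM/LH``, additive in log2 by construction), the
    archetype, log10 abundance, and four localization proportions.
    ``scaling`` holds one row per (age-variant protein, strain) with the
    wild-type age direction and the planted younger/unchanged/older call.
    """

    proteins: pd.DataFrame
    scaling: pd.DataFrame
    params: SimulationParams

    @property
    def variant_ids(self) -> pd.Index:
        return self.proteins.index[self.proteins["is_age_variant"]]

    def true_changes(self) -> pd.DataFrame:
        return self.proteins[[f"true_log2_{p}" for p in PAIRS]].rename(
            columns=lambda c: c.replace("true_log2_", "")
        )


def simulate_proteome(
    params: SimulationParams,
) -> tuple[list[pd.DataFrame], SyntheticTruth]:
    """Generate one protein-group table per replicate plus ground truth.

    Each replicate table is in the canonical column layout of
    :mod:`proteoage.io` (one row per protein group, linear SILAC ratios,
    channel intensities, razor/unique peptide counts, reverse/contaminant
    flags) and can be written to MaxQuant-dialect TSV with
    :func:`proteoage.io.write_protein_groups`.

    Observed log2 M/H and L/M ratios are the planted changes plus
    independent noise with intensity-dependent SD; the observed L/H ratio
    is their sum plus a small independent error, so log-ratio additivity
    holds exactly in truth but only softly in observations.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    ids = pd.Index([f"PG{i:05d}" for i in range(1, n + 1)], name="protein")
    genes = [f"gene-{i:05d}" for i in range(1, n + 1)]

    log10_int = rng.normal(params.abundance_log10_mean, params.abundance_log10_sd, n)

    n_var = int(round(params.frac_age_variant * n))
    is_var = np.zeros(n, dtype=bool)
    archetype = np.zeros(n, dtype=int)
    if n_var:
        var_idx = rng.choice(n, size=n_var, replace=False)
        is_var[var_idx] = True
        archetype[var_idx] = (
            rng.choice(6, size=n_var, p=np.asarray(params.archetype_weights)) + 1
        )
    signs = np.array([ARCHETYPE_SIGNS.get(a, (0, 0)) for a in archetype], dtype=float)
    true_mh = signs[:, 0] * params.effect_size_log2
    true_lm = signs[:, 1] * params.effect_size_log2
    true_lh = true_mh + true_lm

    localization = rng.dirichlet(np.ones(4), size=n)

    # Wild-type age direction: overall day10/day1 change, falling back to
    # the early interval for the two archetypes whose L/H nets to zero.
    overall = np.where(true_lh != 0, true_lh, true_mh)
    wt_direction = np.where(overall > 0, "up", np.where(overall < 0, "down", "none"))

    scaling_rows = []
    var_ids = ids[is_var]
    for strain, props in params.strains.items():
        calls = rng.choice(SCALING_CALLS, size=n_var, p=np.asarray(props, dtype=float))
        for pid, d, c in zip(var_ids, wt_direction[is_var], calls):
            scaling_rows.append((pid, strain, d, c))
    scaling = pd.DataFrame(
        scaling_rows, columns=["protein", "strain", "wt_direction", "call"]
    )

    truth_df = pd.DataFrame(
        {
            "is_age_variant": is_var,
            "archetype": archetype,
            "true_log2_MH": true_mh,
            "true_log2_LM": true_lm,
            "true_log2_LH": true_lh,
            "log10_intensity": log10_int,
            "wt_direction": wt_direction,
            **{f"loc_{c}": localization[:, i] for i, c in enumerate(COMPARTMENTS)},
        },
        index=ids,
    )

    sd = params.noise_sd(log10_int)
    n_decoy = int(round(params.decoy_rate * n))
    tables: list[pd.DataFrame] = []
    for _ in range(params.n_replicates):
        obs_mh = true_mh + rng.normal(0.0, sd)
        obs_lm = true_lm + rng.normal(0.0, sd)
        obs_lh = obs_mh + obs_lm + rng.normal(0.0, sd / 4.0)
        rep_int = 10.0 ** (log10_int + rng.normal(0.0, 0.1, n))
        intensity_h = rep_int
        intensity_m = rep_int * 2.0**obs_mh
        intensity_l = rep_int * 2.0**obs_lh
        peptides = rng.poisson(np.maximum(0.2, 1.5 * (log10_int - 4.0)))

        ratio_mh = 2.0**obs_mh
        ratio_lm = 2.0**obs_lm
        ratio_lh = 2.0**obs_lh
        if params.missing_rate > 0:
            for arr in (ratio_mh, ratio_lm, ratio_lh):
                arr[rng.random(n) < params.missing_rate] = np.nan

        df = pd.DataFrame(
            {
                "protein": ids,
                "gene": genes,
                "unique_peptides": peptides,
                "intensity_H": intensity_h,
                "intensity_M": intensity_m,
                "intensity_L": intensity_l,
                "ratio_MH": ratio_mh,
                "ratio_LM": ratio_lm,
                "ratio_LH": ratio_lh,
                "reverse": False,
                "contaminant": False,
            }
        )
        if n_decoy:
            df = pd.concat(
                [df, _decoy_rows(rng, n_decoy, params)], ignore_index=True
            )
        tables.append(df)

    truth = SyntheticTruth(proteins=truth_df, scaling=scaling, params=params)
    return tables, truth


def _decoy_rows(
    rng: np.random.Generator, n_decoy: int, params: SimulationParams
) -> pd.DataFrame:
    """Reverse-hit and contaminant rows, flagged as MaxQuant would."""
    rows = []
    for kind in ("REV", "CON"):
        inten = 10.0 ** rng.normal(
            params.abundance_log10_mean, params.abundance_log10_sd, n_decoy
        )
        for j in range(n_decoy):
            rows.append(
                {
                    "protein": f"{kind}__X{j:04d}",
                    "gene": "",
                    "unique_peptides": int(rng.integers(1, 6)),
                    "intensity_H": inten[j],
                    "intensity_M": inten[j],
                    "intensity_L": inten[j],
                    "ratio_MH": 1.0,
                    "ratio_LM": 1.0,
                    "ratio_LH": 1.0,
                    "reverse": kind == "REV",
                    "contaminant": kind == "CON",
                }
            )
    return pd.DataFrame(rows)


def simulate_fraction_table(
    truth: SyntheticTruth,
    seed: int = 0,
    noise_cv: float = 0.2,
) -> pd.DataFrame:
    """Per-protein intensities over the four sub-cellular fractions.

    Expected fraction proportions equal the truth's localization
    proportions; multiplicative gamma noise (unit mean, CV ``noise_cv``)
    perturbs individual fraction intensities. ``noise_cv=0`` reproduces
    the planted proportions exactly.
    """
    rng = np.random.default_rng(seed)
    props = truth.proteins[[f"loc_{c}" for c in COMPARTMENTS]].to_numpy()
    total = 10.0 ** truth.proteins["log10_intensity"].to_numpy()
    expected = props * total[:, None]
    if noise_cv > 0:
        shape = 1.0 / noise_cv**2
        g = rng.gamma(shape, 1.0 / shape, size=expected.shape)
        observed = expected * g
    else:
        observed = expected
    return pd.DataFrame(observed, index=truth.proteins.index, columns=COMPARTMENTS)


def simulate_mutant_ratios(
    truth: SyntheticTruth,
    strain_config: dict[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
    offset_log2: float = 1.0,
    noise_sd: float = 0.2,
) -> pd.DataFrame:
    """Mutant/wild-type log2 ratios at a matched age per age-variant protein.

    The planted offset is 0 for "unchanged" calls and ``±offset_log2``
    otherwise, with the sign chosen so that a "younger" call moves the
    mutant toward the young wild-type level given the protein's wild-type
    age direction (e.g. an age-increasing protein that is younger in the
    mutant carries a negative log2 ratio). ``noise_sd=0`` yields the
    offsets exactly.
    """
    strains = (
        truth.scaling["strain"].unique().tolist()
        if strain_config is None
        else list(strain_config)
    )
    rng = np.random.default_rng(seed)
    sub = truth.scaling[truth.scaling["strain"].isin(strains)].copy()
    dir_sign = np.where(sub["wt_direction"] == "up", 1.0, -1.0)
    call_sign = np.where(
        sub["call"] == "unchanged",
        0.0,
        np.where(sub["call"] == "older", 1.0, -1.0),
    )
    offsets = dir_sign * call_sign * offset_log2
    noise = rng.normal(0.0, noise_sd, len(sub)) if noise_sd > 0 else 0.0
    sub["log2_mutant_vs_wt"] = offsets + noise
    return sub.reset_index(drop=True)


def simulate_reporter_stack(
    n_foci: int,
    focus_intensity: float = 30.0,
    diffuse_level: float = 1.0,
    shape: tuple[int, int, int] = (81, 128, 128),
    seed: int = 0,
    spot_sigma_xy: float = 1.5,
    spot_sigma_z: float = 2.0,
    noise_sd: float = 0.5,
    amp_jitter: float = 0.3,
    min_separation: float | None = None,
    diffuse_fraction: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Reporter z-stack: Gaussian foci over a uniform diffuse background.

    Foci are well-separated 3D Gaussian spots whose z-centers sit within
    one section of the middle plane (the imaging focal plane), so all foci
    are resolvable on a single designated section, as in the reporter
    assay the stack emulates. Additive zero-mean Gaussian noise is applied
    and the result clipped at zero.

    If ``diffuse_fraction`` is given, the foci amplitudes are rescaled so
    that exactly that fraction of the summed noiseless intensity is
    diffuse (the background level itself is left alone, keeping the
    noise-to-background ratio fixed). Returns ``(stack, truth)`` where
    ``truth`` records foci centers and the exact cytoplasmic (diffuse)
    fraction of the generated components.
    """
    if n_foci < 0:
        raise ValueError("n_foci must be nonnegative")
    nz, ny, nx = shape
    if min_separation is None:
        min_separation = 6.0 * spot_sigma_xy
    rng = np.random.default_rng(seed)

    margin = math.ceil(4 * spot_sigma_xy) + 2
    centers: list[tuple[float, float, float]] = []
    tries = 0
    while len(centers) < n_foci:
        tries += 1
        if tries > 10000 * max(1, n_foci):
            raise ValueError("could not place well-separated foci; reduce n_foci")
        y = rng.uniform(margin, ny - margin)
        x = rng.uniform(margin, nx - margin)
        if all(
            (y - cy) ** 2 + (x - cx) ** 2 >= min_separation**2
            for _, cy, cx in centers
        ):
            z = (nz - 1) / 2.0 + rng.uniform(-1.0, 1.0)
            centers.append((z, y, x))

    foci = np.zeros(shape, dtype=float)
    amps = focus_intensity * (
        1.0 + amp_jitter * rng.uniform(-1.0, 1.0, size=n_foci)
    )
    zz = np.arange(nz, dtype=float)
    for (cz, cy, cx), amp in zip(centers, amps):
        half = math.ceil(4 * spot_sigma_xy)
        y0, y1 = int(cy) - half, int(cy) + half + 1
        x0, x1 = int(cx) - half, int(cx) + half + 1
        yy = np.arange(y0, y1, dtype=float)
        xx = np.arange(x0, x1, dtype=float)
        gz = np.exp(-((zz - cz) ** 2) / (2 * spot_sigma_z**2))
        gy = np.exp(-((yy - cy) ** 2) / (2 * spot_sigma_xy**2))
        gx = np.exp(-((xx - cx) ** 2) / (2 * spot_sigma_xy**2))
        foci[:, y0:y1, x0:x1] += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]

    foci_sum = float(foci.sum())
    diffuse = np.full(shape, float(diffuse_level))
    diffuse_sum = float(diffuse.sum())
    if diffuse_fraction is not None:
        if not 0 < diffuse_fraction <= 1:
            raise ValueError("diffuse_fraction must lie in (0, 1]")
        if n_foci == 0 and diffuse_fraction < 1:
            raise ValueError("diffuse_fraction < 1 requires at least one focus")
        if n_foci:
            if diffuse_level <= 0:
                raise ValueError("diffuse_fraction needs a positive diffuse_level")
            scale = (
                (1.0 - diffuse_fraction) * diffuse_sum
                / (diffuse_fraction * foci_sum)
            )
            foci *= scale
            amps = amps * scale
            foci_sum = float(foci.sum())

    total = foci_sum + diffuse_sum
    if total <= 0:
        raise ValueError("stack has no signal; set diffuse_level or n_foci")

    stack = diffuse + foci
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, size=shape)
        np.clip(stack, 0.0, None, out=stack)

    truth = {
        "centers": centers,
        "amplitudes": amps.tolist(),
        "n_foci": n_foci,
        "foci_sum": foci_sum,
        "diffuse_sum": diffuse_sum,
        "cytoplasmic_fraction": diffuse_sum / total,
        "designated_section": (nz - 1) // 2,
        "z_spacing_um": 0.5,
    }
    return stack, truth


def simulate_gene_sets(
    truth: SyntheticTruth,
    set_size: int = 17,
    n_outliers: int = 2,
    seed: int = 0,
):
    """Two gene sets against the simulated proteome: one age-up-enriched
    set (with a few planted opposite-direction outlier members, mimicking
    genuine biological exceptions inside a shifted pathway) and one null
    set drawn uniformly.

    Returns a list of :class:`proteoage.geneset.GeneSet`.
    """
    from .geneset import GeneSet

    rng = np.random.default_rng(seed)
    up_ids = truth.proteins.index[
        truth.proteins["is_age_variant"] & (truth.proteins["true_log2_LH"] > 0)
    ]
    down_ids = truth.proteins.index[
        truth.proteins["is_age_variant"] & (truth.proteins["true_log2_LH"] < 0)
    ]
    n_up = set_size - n_outliers
    if len(up_ids) < n_up or len(down_ids) < n_outliers:
        raise ValueError("not enough age-variant proteins to build gene sets")
    members = list(rng.choice(up_ids, size=n_up, replace=False)) + list(
        rng.choice(down_ids, size=n_outliers, replace=False)
    )
    null_members = list(
        rng.choice(truth.proteins.index, size=set_size, replace=False)
    )
    return [
        GeneSet("age_up_set", tuple(members), "synthetic: planted age-up"),
        GeneSet("null_set", tuple(null_members), "synthetic: uniform draw"),
    ]
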