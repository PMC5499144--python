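"""Synthetic screen generator with known ground truth.

Emulates a paired genome-wide fitness screen: a deletion library crossed
into a control background and into a query-mutation background, spotted as
replicate cultures on 384-position plates and imaged over several days.
Cultures grow logistically; readings carry multiplicative log-normal noise;
a small fraction of cultures are dead.  The query mutation multiplies every
strain's fitness by a common slope m (genetic independence), except for a
planted minority of suppressors (fitness above the independence prediction)
and enhancers (below it).  An up-down (UD) treatment — acute damage pulses
followed by recovery — is modelled as an additional viability multiplier on
query-background fitness.

Planted effects act on the growth rate r with K and G0 held at their
baseline values: MDP = log2(K/G0) is then unchanged and MDR is proportional
to r, so a fitness effect of size s maps exactly to multiplying r by s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidParameterError
from .growth import GrowthCurve, INTENSITY_FLOOR, compute_fitness, LogisticFit, _logistic

DEFAULT_TIMEPOINTS = tuple(np.linspace(0.0, 5.0, 15))


@dataclass
class SimulationConfig:
    """Conditions of one simulated paired screen.

    Baseline (K, r, G0) are drawn per gene from log-normal distributions
    given as (location, scale) of the underlying normal; K and G0 in
    intensity units, r in 1/day.  ``query_slope`` is the global multiplicative
    fitness effect of the query mutation (the independence slope m).
    """

    n_genes: int = 1000
    n_replicates: int = 8
    timepoints: tuple = DEFAULT_TIMEPOINTS
    plate_geometry: tuple = (16, 24)
    K_dist: tuple = (np.log(0.2), 0.15)
    r_dist: tuple = (np.log(3.0), 0.25)
    G0_dist: tuple = (np.log(0.003), 0.2)
    noise_sigma: float = 0.02
    query_slope: float = 0.5
    planted_fraction_sup: float = 0.05
    planted_fraction_enh: float = 0.05
    effect_size_sup: float = 1.8
    effect_size_enh: float = 0.5
    dead_fraction: float = 0.02
    treatment: str = "chronic"
    ud_viability_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        v = []
        if not (isinstance(self.n_genes, (int, np.integer)) and self.n_genes > 0):
            v.append(f"n_genes must be a positive integer, got {self.n_genes}")
        if not (isinstance(self.n_replicates, (int, np.integer)) and self.n_replicates > 0):
            v.append(f"n_replicates must be a positive integer, got {self.n_replicates}")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0:
            v.append("timepoints must be non-empty")
        else:
            if tp[0] < 0:
                v.append("timepoints[0] must be >= 0")
            if np.any(np.diff(tp) <= 0):
                v.append("timepoints must be sorted strictly ascending")
        rows, cols = self.plate_geometry
        if rows < 1 or cols < 1:
            v.append(f"plate_geometry must be positive, got {self.plate_geometry}")
        for name in ("K_dist", "r_dist", "G0_dist"):
            loc, scale = getattr(self, name)
            if scale <= 0:
                v.append(f"{name} scale must be > 0, got {scale}")
        if self.G0_dist[0] >= self.K_dist[0]:
            v.append("G0 location must be below K location (inoculum below capacity)")
        if self.noise_sigma < 0:
            v.append(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if not (0 < self.query_slope <= 1):
            v.append(f"query_slope must be in (0, 1], got {self.query_slope}")
        for name in ("planted_fraction_sup", "planted_fraction_enh"):
            val = getattr(self, name)
            if not (0 <= val < 1):
                v.append(f"{name} must be in [0, 1), got {val}")
        if self.planted_fraction_sup + self.planted_fraction_enh >= 1:
            v.append("planted_fraction_sup + planted_fraction_enh must be < 1")
        if self.effect_size_sup < 1:
            v.append(f"effect_size_sup must be >= 1, got {self.effect_size_sup}")
        if not (0 < self.effect_size_enh <= 1):
            v.append(f"effect_size_enh must be in (0, 1], got {self.effect_size_enh}")
        if not (0 <= self.dead_fraction < 1):
            v.append(f"dead_fraction must be in [0, 1), got {self.dead_fraction}")
        if self.treatment not in ("chronic", "UD"):
            v.append(f"treatment must be 'chronic' or 'UD', got {self.treatment!r}")
        if self.ud_viability_scale <= 0:
            v.append(f"ud_viability_scale must be > 0, got {self.ud_viability_scale}")
        if v:
            raise ConfigurationError(v)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoints"] = [float(t) for t in self.timepoints]
        d["plate_geometry"] = list(self.plate_geometry)
        d["K_dist"] = [float(x) for x in self.K_dist]
        d["r_dist"] = [float(x) for x in self.r_dist]
        d["G0_dist"] = [float(x) for x in self.G0_dist]
        return d


@dataclass
class GroundTruth:
    """What the simulator actually planted.

    ``genes`` — one row per gene: orf, gene, label (suppressor/enhancer/none),
    effect (multiplier applied on top of the independence prediction),
    F_true_control, F_true_query, and the gene-level (K, r_control, r_query,
    G0).  ``cultures`` — one row per culture: orf, background, replicate,
    K, r, G0, dead.  ``m_effective`` = query_slope × ud_viability_scale under
    UD, else query_slope: the slope the independence fit should recover.
    """

    genes: pd.DataFrame = field(repr=False)
    cultures: pd.DataFrame = field(repr=False)
    m_true: float = 1.0
    m_effective: float = 1.0
    config: SimulationConfig | None = None

    @property
    def suppressors(self) -> list[str]:
        return list(self.genes.loc[self.genes.label == "suppressor", "orf"])

    @property
    def enhancers(self) -> list[str]:
        return list(self.genes.loc[self.genes.label == "enhancer", "orf"])


def _true_fitness(K: float, r: float, G0: float) -> float:
    return compute_fitness(LogisticFit(K, r, G0, 0.0, 0, "ok")).fitness


def logistic_growth(t, K, r, G0):
    # re-exported for convenience; canonical definition lives in growth
    from .growth import logistic_growth as _lg
    return _lg(t, K, r, G0)


def simulate_culture(params: tuple[float, float, float], timepoints,
                     noise_sigma: float, dead: bool = False,
                     seed: int | np.random.Generator = 0,
                     metadata: dict | None = None) -> GrowthCurve:
    """Simulate one culture's intensity series.

    Intensities are the logistic trajectory times exp(ε) with
    ε ~ N(0, noise_sigma²) i.i.d. per timepoint, floored at 1e-6 intensity
    units.  A dead culture stays at its inoculum level (times noise).  A
    fixed integer seed gives bit-identical output.
    """
    K, r, G0 = params
    if noise_sigma < 0:
        raise InvalidParameterError(f"noise_sigma must be >= 0, got {noise_sigma}")
    t = np.asarray(timepoints, dtype=float)
    if t.size == 0:
        raise InvalidParameterError("timepoints must be non-empty")
    # validate parameters via the public kernel
    from .growth import logistic_growth as _lg
    _lg(0.0, K, r, G0)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signal = np.full_like(t, G0) if dead else _logistic(t, K, r, G0)
    eps = rng.normal(0.0, noise_sigma, size=t.size) if noise_sigma > 0 else np.zeros(t.size)
    intensities = np.maximum(signal * np.exp(eps), INTENSITY_FLOOR)

    meta = {
        "screen_id": "SIM", "plate_barcode": "SIM_P0001", "row": 1, "column": 1,
        "orf": "YSIM0001C", "gene": "SIM1", "background": "control",
        "treatment": "chronic",
    }
    if metadata:
        meta.update(metadata)
    return GrowthCurve(times=t, intensities=intensities, **meta)


def _plate_position(index: int, geometry: tuple[int, int]) -> tuple[int, int, int]:
    """Sequential row-major fill of 1-based plate coordinates."""
    rows, cols = geometry
    per_plate = rows * cols
    plate = index // per_plate
    within = index % per_plate
    return plate + 1, within // cols + 1, within % cols + 1


def simulate_screen_pair(config: SimulationConfig
                         ) -> tuple[list[GrowthCurve], list[GrowthCurve], GroundTruth]:
    """Generate paired control and query screens plus their ground truth.

    Per-gene query fitness targets are m × F_control, multiplied by the
    planted effect size for suppressor/enhancer genes and by
    ``ud_viability_scale`` under UD treatment; targets are realized exactly
    (before noise) by scaling r.  Planted gene counts follow
    floor(fraction × n_genes), suppressors assigned before enhancers from a
    seed-shuffled gene order.
    """
    config.validate()
    n = config.n_genes
    ss = np.random.SeedSequence(config.seed)
    rng_params, rng_labels, rng_dead, rng_noise_c, rng_noise_q = (
        np.random.default_rng(s) for s in ss.spawn(5))

    orfs = [f"YSIM{i + 1:04d}C" for i in range(n)]
    genes = [f"SIM{i + 1}" for i in range(n)]

    K = np.exp(rng_params.normal(*config.K_dist, size=n))
    r_ctrl = np.exp(rng_params.normal(*config.r_dist, size=n))
    G0 = np.exp(rng_params.normal(*config.G0_dist, size=n))
    G0 = np.minimum(G0, K / 4.0)  # keep inoculum well below capacity

    n_sup = int(np.floor(config.planted_fraction_sup * n))
    n_enh = int(np.floor(config.planted_fraction_enh * n))
    order = rng_labels.permutation(n)
    labels = np.array(["none"] * n, dtype=object)
    labels[order[:n_sup]] = "suppressor"
    labels[order[n_sup:n_sup + n_enh]] = "enhancer"
    effects = np.ones(n)
    effects[labels == "suppressor"] = config.effect_size_sup
    effects[labels == "enhancer"] = config.effect_size_enh

    ud = config.ud_viability_scale if config.treatment == "UD" else 1.0
    m_eff = config.query_slope * ud
    r_query = r_ctrl * m_eff * effects  # fitness scales exactly with r

    F_ctrl = np.array([_true_fitness(K[i], r_ctrl[i], G0[i]) for i in range(n)])
    F_query = F_ctrl * m_eff * effects

    n_rep = config.n_replicates
    dead_ctrl = rng_dead.random((n, n_rep)) < config.dead_fraction
    dead_query = rng_dead.random((n, n_rep)) < config.dead_fraction

    tag = f"SIM{config.seed:05d}"
    screens = []
    culture_rows = []
    for background, r_vec, dead_mat, rng_noise in (
            ("control", r_ctrl, dead_ctrl, rng_noise_c),
            ("query", r_query, dead_query, rng_noise_q)):
        screen_id = f"{tag}_{'CTRL' if background == 'control' else 'QRY'}"
        curves = []
        idx = 0
        for i in range(n):
            for rep in range(n_rep):
                plate, row, col = _plate_position(idx, config.plate_geometry)
                dead = bool(dead_mat[i, rep])
                curve = simulate_culture(
                    (K[i], r_vec[i], G0[i]), config.timepoints,
                    config.noise_sigma, dead=dead, seed=rng_noise,
                    metadata={
                        "screen_id": screen_id,
                        "plate_barcode": f"{screen_id}_P{plate:04d}",
                        "row": row, "column": col,
                        "orf": orfs[i], "gene": genes[i],
                        "background": background,
                        "treatment": config.treatment,
                    })
                curves.append(curve)
                culture_rows.append({
                    "orf": orfs[i], "background": background, "replicate": rep + 1,
                    "K": K[i], "r": r_vec[i], "G0": G0[i], "dead": dead,
                })
                idx += 1
        screens.append(curves)

    truth = GroundTruth(
        genes=pd.DataFrame({
            "orf": orfs, "gene": genes, "label": labels, "effect": effects,
            "F_true_control": F_ctrl, "F_true_query": F_query,
            "K": K, "r_control": r_ctrl, "r_query": r_query, "G0": G0,
        }),
        cultures=pd.DataFrame(culture_rows),
        m_true=config.query_slope,
        m_effective=m_eff,
        config=config,
    )
    return screens[0], screens[1], truth


def simulate_profile_matrix(n_genes: int = 500, n_screens: int = 12,
                            module_size: int = 10, noise_sd: float = 0.3,
                            seed: int = 3):
    """Genes × screens value matrix with one planted co-functional module.

    Background genes get i.i.d. standard-normal values per screen; the
    ``module_size`` module genes share a common standard-normal profile plus
    gene-specific N(0, noise_sd²) noise.  Returns ``(ProfileMatrix, module
    orfs)``; used to validate profile-similarity ranking.
    """
    from .profiles import ProfileMatrix

    rng = np.random.default_rng(seed)
    orfs = [f"YSIM{i + 1:04d}C" for i in range(n_genes)]
    screens = [f"SCR{j + 1:02d}|chronic" for j in range(n_screens)]
    values = rng.normal(size=(n_genes, n_screens))
    members = sorted(rng.choice(n_genes, size=module_size, replace=False))
    shared = rng.normal(size=n_screens)
    for i in members:
        values[i] = shared + rng.normal(0.0, noise_sd, size=n_screens)
    df = pd.DataFrame(values, index=pd.Index(orfs, name="orf"), columns=screens)
    genes = {orf: f"SIM{i + 1}" for i, orf in enumerate(orfs)}
    return ProfileMatrix(values=df, value_kind="fitness", gene_names=genes), \
        [orfs[i] for i in members]
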