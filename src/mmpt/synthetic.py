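"""Synthetic cohort generation with known ground truth.

Produces every input the pipeline consumes — per-cell feature tables,
384-well plate layouts, proteome and cytokine matrices, scRNA-seq UMI
counts and clinical outcome tables — from a single seeded configuration,
together with a :class:`GroundTruth` record of what was planted.

Design notes
------------
* Latent features are Gaussian mixtures with one component per cell
  subcluster; subclusters are nested within the four cell classes and
  sample-level subcluster compositions follow one of a small number of
  "mode" vectors (the planted PhenoGroups).
* Treated-well cell counts are Poisson draws whose rates are thinned by
  per-(treatment, class) kill fractions, so expected well fractions —
  and hence expected RCF/PCY — have a closed form (:func:`expected_pcy`).
* Event times are exponential with a log-hazard linear in centered iPCY.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "TreatmentSpec",
    "HazardModel",
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "generate_proteome",
    "generate_validation_pairs",
    "generate_cytokines",
    "generate_scrna",
    "generate_survival",
    "survival_times",
    "expected_class_fractions",
    "expected_pcy",
    "default_modes",
    "write_cohort",
]

CLASSES = ("plasma", "t_cell", "monocyte", "other")

#: Number of subclusters allocated to each class for k = 15.
_DEFAULT_CLASS_SPLIT = {"plasma": 5, "t_cell": 4, "monocyte": 3, "other": 3}

_PLATE_ROWS = "ABCDEFGHIJKLMNOP"
_PLATE_COLS = range(1, 25)

_EXCLUSION_MARKERS = ("S100A8", "CD14", "CD3D", "CD3E", "TRAC", "COL1A2", "C1QA")


@dataclass(frozen=True)
class TreatmentSpec:
    """One screened treatment; combinations carry >1 component."""

    name: str
    kind: str = "compound"  # "compound" or "antibody"
    components: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("compound", "antibody"):
            raise ValueError(f"unknown treatment kind: {self.kind!r}")
        if not self.components:
            object.__setattr__(self, "components", tuple(self.name.split("+")))


@dataclass(frozen=True)
class HazardModel:
    baseline_rate: float = 1.0 / 300.0  # events per day
    log_hr_coef: float = -2.0  # on centered iPCY; negative = sensitive live longer
    censor_rate: float = 0.2

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")


def default_modes(n_subclusters: int = 15, n_modes: int = 3,
                  class_split: Mapping[str, int] | None = None) -> list[np.ndarray]:
    """Fixed, seed-independent composition vectors over subclusters.

    Mode 1 is plasma-rich, mode 2 T-cell-rich, mode 3 balanced; further
    modes interpolate. Within-class weights differ per mode so the modes
    are distinct at subcluster resolution too.
    """
    split = dict(class_split or _scaled_split(n_subclusters))
    class_mix = [
        {"plasma": 0.55, "t_cell": 0.20, "monocyte": 0.15, "other": 0.10},
        {"plasma": 0.15, "t_cell": 0.50, "monocyte": 0.20, "other": 0.15},
        {"plasma": 0.30, "t_cell": 0.25, "monocyte": 0.30, "other": 0.15},
    ]
    while len(class_mix) < n_modes:
        i = len(class_mix)
        class_mix.append({c: (v + 1.0 / len(CLASSES)) / 2
                          for c, v in class_mix[i % 3].items()})
    modes = []
    for m in range(n_modes):
        rng = np.random.default_rng(90210 + m)  # fixed: modes are constants
        vec = []
        for cls in CLASSES:
            w = rng.dirichlet(np.full(split[cls], 2.0))
            vec.extend(class_mix[m][cls] * w)
        modes.append(np.asarray(vec))
    return modes


def _scaled_split(n_subclusters: int) -> dict[str, int]:
    if n_subclusters == 15:
        return dict(_DEFAULT_CLASS_SPLIT)
    if n_subclusters < 4:
        raise ValueError("need at least one subcluster per class")
    base = {c: max(1, round(_DEFAULT_CLASS_SPLIT[c] * n_subclusters / 15))
            for c in CLASSES}
    # fix rounding drift
    while sum(base.values()) > n_subclusters:
        base[max(base, key=base.get)] -= 1
    while sum(base.values()) < n_subclusters:
        base[min(base, key=base.get)] += 1
    return base


def _default_panel() -> tuple[TreatmentSpec, ...]:
    return (
        TreatmentSpec("bortezomib"),
        TreatmentSpec("dexamethasone"),
        TreatmentSpec("lenalidomide"),
        TreatmentSpec("bortezomib+dexamethasone"),
        TreatmentSpec("daratumumab", kind="antibody"),
        TreatmentSpec("elotuzumab", kind="antibody"),
    )


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort."""

    n_samples: int = 20
    n_cells_per_well: int = 1300  # desk scale; the assay seeds 13,000
    n_latent_features: int = 512
    n_subclusters: int = 15
    phenogroup_modes: list[np.ndarray] | None = None
    mode_assignment: Sequence[int] | None = None  # per-sample mode index
    drug_panel: tuple[TreatmentSpec, ...] = field(default_factory=_default_panel)
    kill_fractions: Mapping[str, Mapping[str, float | np.ndarray]] | None = None
    concentrations: tuple[float, ...] = (0.1, 1.0, 10.0)
    n_replicates_compound: int = 3
    n_replicates_antibody: int = 4
    n_dmso_wells: int = 8
    n_isotype_wells: int = 4
    latent_separation: float = 6.0
    marker_separation: float = 6.0
    myeloma_fraction_by_mode: tuple[float, ...] = (0.7, 0.25, 0.5)
    t_activated_fraction: float = 0.25
    contact_fraction: float = 0.0
    contact_radius_um: float = 15.0
    well_extent_um: float = 1000.0
    n_proteins: int = 2000
    n_signature_proteins: int = 100
    proteome_effect: float = 0.8
    proteome_noise_sd: float = 1.0
    proteome_missing_rate: float = 0.05
    hazard_model: HazardModel = field(default_factory=HazardModel)
    seed: int = 0

    def __post_init__(self):
        if self.phenogroup_modes is None:
            self.phenogroup_modes = default_modes(self.n_subclusters)
        for i, mode in enumerate(self.phenogroup_modes):
            mode = np.asarray(mode, dtype=float)
            if mode.size != self.n_subclusters:
                raise ValueError(
                    f"mode {i} has {mode.size} entries, expected {self.n_subclusters}")
            if abs(mode.sum() - 1.0) > 1e-8:
                raise ValueError(f"composition mode {i} does not sum to 1")
            self.phenogroup_modes[i] = mode
        if self.kill_fractions is None:
            self.kill_fractions = _default_kills(self.drug_panel)
        for trt, per_class in self.kill_fractions.items():
            for cls, val in per_class.items():
                arr = np.asarray(val, dtype=float)
                if np.any((arr < 0) | (arr > 1)):
                    raise ValueError(
                        f"kill fraction out of [0, 1] for {trt}/{cls}")
        if self.n_signature_proteins > self.n_proteins:
            raise ValueError("n_signature_proteins exceeds n_proteins")

    @property
    def subcluster_classes(self) -> list[str]:
        split = _scaled_split(self.n_subclusters)
        out = []
        for cls in CLASSES:
            out.extend([cls] * split[cls])
        return out


def _default_kills(panel) -> dict[str, dict[str, float]]:
    kills = {}
    for i, trt in enumerate(panel):
        k = 0.2 + 0.1 * (i % 4)
        kills[trt.name] = {"myeloma": k, "small": k * 0.3}
    return kills


@dataclass
class GroundTruth:
    """What was planted, per sample / cell / patient."""

    phenogroup: dict[str, int]
    mode_vectors: list[list[float]]
    fraction_big: dict[str, float]
    kill_fractions: dict[str, dict[str, list[float]]]
    expected_pcy: dict[str, dict[str, float]]  # sample -> treatment -> PCY
    signature_up: list[str] = field(default_factory=list)
    signature_down: list[str] = field(default_factory=list)
    big_like_cells: dict[str, bool] = field(default_factory=dict)
    hazard_group: dict[str, str] = field(default_factory=dict)
    true_ipcy: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        def _clean(o):
            if isinstance(o, dict):
                return {str(k): _clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [_clean(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.bool_):
                return bool(o)
            return o
        return json.dumps(_clean(self.__dict__), indent=1)


@dataclass
class Cohort:
    config: CohortConfig
    cells: pd.DataFrame
    layout: pd.DataFrame
    proteome: pd.DataFrame | None
    validation_big: pd.DataFrame | None
    validation_small: pd.DataFrame | None
    cytokines: pd.DataFrame | None
    cytokine_status: pd.DataFrame | None
    scrna_counts: pd.DataFrame | None
    scrna_genes: pd.DataFrame | None
    scrna_cells: pd.DataFrame | None
    clinical: pd.DataFrame | None
    truth: GroundTruth


# ---------------------------------------------------------------------------
# closed-form expectations


def _kill_for(config: CohortConfig, treatment: str, cls: str, subtype: str,
              sample_idx: int) -> float:
    per_class = config.kill_fractions.get(treatment, {})

    def _get(key):
        val = per_class.get(key)
        if val is None:
            return None
        arr = np.asarray(val, dtype=float)
        return float(arr if arr.ndim == 0 else arr[sample_idx])

    if cls == "plasma":
        v = _get("myeloma" if subtype == "myeloma" else "small")
        if v is None:
            v = _get("plasma")
        return v or 0.0
    return _get(cls) or 0.0


def expected_class_fractions(config: CohortConfig, sample_idx: int,
                             treatment: str | None) -> dict[str, float]:
    """Expected well composition over {myeloma, small, t_cell, monocyte, other}.

    ``treatment=None`` gives the untreated (control) composition. Ratios of
    expectations; exact as cell counts grow.
    """
    mode = config.phenogroup_modes[_mode_of(config, sample_idx)]
    cls_of = config.subcluster_classes
    fb = _fraction_big(config, sample_idx)
    weights = {}
    for j, p in enumerate(mode):
        cls = cls_of[j]
        if cls == "plasma":
            for subtype, share in (("myeloma", fb), ("small", 1 - fb)):
                kill = 0.0 if treatment is None else _kill_for(
                    config, treatment, cls, subtype, sample_idx)
                weights[subtype] = weights.get(subtype, 0.0) + p * share * (1 - kill)
        else:
            kill = 0.0 if treatment is None else _kill_for(
                config, treatment, cls, "", sample_idx)
            weights[cls] = weights.get(cls, 0.0) + p * (1 - kill)
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def expected_pcy(config: CohortConfig, sample_idx: int, treatment: str,
                 target: str = "myeloma") -> float:
    """Closed-form PCY = 1 - E[fraction_treated] / E[fraction_control]."""
    ctrl = expected_class_fractions(config, sample_idx, None)
    trt = expected_class_fractions(config, sample_idx, treatment)
    if ctrl[target] == 0:
        return float("nan")
    return 1.0 - trt[target] / ctrl[target]


def _mode_of(config: CohortConfig, sample_idx: int) -> int:
    if config.mode_assignment is not None:
        return int(config.mode_assignment[sample_idx])
    return sample_idx % len(config.phenogroup_modes)


def _fraction_big(config: CohortConfig, sample_idx: int) -> float:
    base = config.myeloma_fraction_by_mode[
        _mode_of(config, sample_idx) % len(config.myeloma_fraction_by_mode)]
    # deterministic per-sample jitter, independent of draw order
    jitter = np.random.default_rng(
        np.random.SeedSequence((config.seed, 424242, sample_idx)))
    return float(np.clip(base + jitter.uniform(-0.1, 0.1), 0.05, 0.95))


# ---------------------------------------------------------------------------
# plate layout


def build_plate_layout(config: CohortConfig, rng: np.random.Generator,
                       sample_id: str) -> pd.DataFrame:
    """Randomized 384-well layout for one sample's plate."""
    rows = []
    for trt in config.drug_panel:
        n_rep = (config.n_replicates_antibody if trt.kind == "antibody"
                 else config.n_replicates_compound)
        for conc in config.concentrations:
            for rep in range(1, n_rep + 1):
                rows.append((trt.name, trt.kind, conc, rep, "none"))
    for rep in range(1, config.n_dmso_wells + 1):
        rows.append(("DMSO", "control", 0.0, rep, "dmso"))
    for rep in range(1, config.n_isotype_wells + 1):
        rows.append(("isotype", "control", 0.0, rep, "isotype"))
    all_wells = [f"{r}{c:02d}" for r in _PLATE_ROWS for c in _PLATE_COLS]
    if len(rows) > len(all_wells):
        raise ValueError("treatment layout exceeds 384 wells")
    wells = rng.choice(all_wells, size=len(rows), replace=False)
    df = pd.DataFrame(rows, columns=["treatment", "drug_class", "concentration_um",
                                     "replicate", "control_type"])
    df.insert(0, "well_id", wells)
    df.insert(0, "sample_id", sample_id)
    return df.sort_values("well_id", ignore_index=True)


# ---------------------------------------------------------------------------
# cells


def _marker_mu(positive: bool, sep: float) -> float:
    # log10 intensity means; sd below is 0.15, so sep is in units of sd
    return 1.0 + (sep * 0.15 if positive else 0.0)


def _generate_well_cells(config: CohortConfig, rng: np.random.Generator,
                         sample_idx: int, sample_id: str, well_id: str,
                         treatment: str | None, latent_means: np.ndarray,
                         ) -> pd.DataFrame:
    mode = config.phenogroup_modes[_mode_of(config, sample_idx)]
    cls_of = config.subcluster_classes
    fb = _fraction_big(config, sample_idx)
    n_target = config.n_cells_per_well

    sub_idx, subtypes = [], []
    for j, p in enumerate(mode):
        cls = cls_of[j]
        if cls == "plasma":
            groups = (("myeloma", p * fb), ("small", p * (1 - fb)))
        else:
            groups = (("", p),)
        for subtype, w in groups:
            kill = 0.0 if treatment is None else _kill_for(
                config, treatment, cls, subtype, sample_idx)
            n = rng.poisson(n_target * w * (1 - kill))
            sub_idx.extend([j] * n)
            subtypes.extend([subtype] * n)
    n = len(sub_idx)
    if n == 0:
        return pd.DataFrame()
    sub_idx = np.asarray(sub_idx)
    classes = np.asarray(cls_of, dtype=object)[sub_idx]

    sep = config.marker_separation
    sd = 0.15
    markers = {}
    plasma = classes == "plasma"
    tc = classes == "t_cell"
    mono = classes == "monocyte"
    # plasma cells: 80% double-positive, 10% CD138-only, 10% CD319-only
    u = rng.uniform(size=n)
    cd138_pos = plasma & (u < 0.9)
    cd319_pos = plasma & ((u < 0.8) | (u >= 0.9))
    for ch, pos in (("CD138", cd138_pos), ("CD319", cd319_pos),
                    ("CD3", tc), ("CD14", mono)):
        mu = np.where(pos, _marker_mu(True, sep), _marker_mu(False, sep))
        markers[ch] = 10 ** rng.normal(mu, sd)
    markers["DAPI"] = 10 ** rng.normal(_marker_mu(True, sep), sd, size=n)

    diameter = rng.normal(9.0, 1.0, size=n)
    subtypes = np.asarray(subtypes, dtype=object)
    big = subtypes == "myeloma"
    small = subtypes == "small"
    diameter[big] = rng.normal(14.0, 1.0, size=int(big.sum()))
    diameter[small] = rng.normal(8.5, 1.0, size=int(small.sum()))
    diameter = np.clip(diameter, 4.0, None)

    t_sub = np.full(n, "none", dtype=object)
    act = tc & (rng.uniform(size=n) < config.t_activated_fraction)
    t_sub[act] = "activated"
    t_sub[tc & ~act] = "conventional"

    x = rng.uniform(0, config.well_extent_um, size=n)
    y = rng.uniform(0, config.well_extent_um, size=n)
    if config.contact_fraction > 0 and big.any():
        eff = np.flatnonzero(t_sub == "activated")
        n_move = int(round(config.contact_fraction * eff.size))
        if n_move:
            movers = rng.choice(eff, size=n_move, replace=False)
            anchors = rng.choice(np.flatnonzero(big), size=n_move)
            r = rng.uniform(0, config.contact_radius_um * 0.9, size=n_move)
            theta = rng.uniform(0, 2 * np.pi, size=n_move)
            x[movers] = np.clip(x[anchors] + r * np.cos(theta),
                                0, config.well_extent_um)
            y[movers] = np.clip(y[anchors] + r * np.sin(theta),
                                0, config.well_extent_um)

    latent = (latent_means[sub_idx]
              + rng.standard_normal((n, config.n_latent_features)))

    df = pd.DataFrame({
        "sample_id": sample_id,
        "well_id": well_id,
        "cell_id": [f"{sample_id}:{well_id}:{i}" for i in range(n)],
        "cell_class": classes,
        "class_confidence": rng.beta(8.0, 2.0, size=n),
        "plasma_subtype": np.where(plasma, subtypes, "none"),
        "t_subtype": t_sub,
        "true_subcluster": sub_idx,
        "x_um": x,
        "y_um": y,
        "diameter_um": diameter,
    })
    for ch, v in markers.items():
        df[ch] = v
    lat = pd.DataFrame(latent,
                       columns=[f"latent_{i}" for i in range(config.n_latent_features)])
    return pd.concat([df, lat.set_index(df.index)], axis=1)


def generate_cohort(config: CohortConfig, *, with_omics: bool = True) -> Cohort:
    """Generate a complete synthetic cohort.

    Fully determined by ``config.seed``. Set ``with_omics=False`` to skip
    proteome / cytokine / scRNA / clinical generation (faster for tests
    that only need cells + layouts).
    """
    root = np.random.SeedSequence(config.seed)
    keys = root.spawn(6)
    rng_layout = np.random.default_rng(keys[0])
    rng_cells = np.random.default_rng(keys[1])

    latent_means = (np.random.default_rng(keys[2])
                    .standard_normal((config.n_subclusters, config.n_latent_features)))
    norms = np.linalg.norm(latent_means, axis=1, keepdims=True)
    latent_means = latent_means / norms * config.latent_separation

    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    layouts, cell_frames = [], []
    for i, sid in enumerate(sample_ids):
        layout = build_plate_layout(config, rng_layout, sid)
        layouts.append(layout)
        for rec in layout.itertuples(index=False):
            trt = None if rec.control_type != "none" else rec.treatment
            cell_frames.append(_generate_well_cells(
                config, rng_cells, i, sid, rec.well_id, trt, latent_means))
    cells = pd.concat(cell_frames, ignore_index=True)
    layout = pd.concat(layouts, ignore_index=True)

    truth = GroundTruth(
        phenogroup={sid: _mode_of(config, i) for i, sid in enumerate(sample_ids)},
        mode_vectors=[list(map(float, m)) for m in config.phenogroup_modes],
        fraction_big={sid: _fraction_big(config, i)
                      for i, sid in enumerate(sample_ids)},
        kill_fractions={
            trt: {cls: list(np.broadcast_to(np.asarray(v, dtype=float),
                                            (config.n_samples,)))
                  for cls, v in per.items()}
            for trt, per in config.kill_fractions.items()},
        expected_pcy={sid: {t.name: expected_pcy(config, i, t.name)
                            for t in config.drug_panel}
                      for i, sid in enumerate(sample_ids)},
    )

    proteome = vbig = vsmall = cyto = cyto_status = None
    counts = genes = scmeta = clinical = None
    if with_omics:
        fb = pd.Series(truth.fraction_big)
        proteome, up, down, vbig, vsmall = generate_proteome(
            fb, n_proteins=config.n_proteins,
            n_signature=config.n_signature_proteins,
            effect=config.proteome_effect, noise_sd=config.proteome_noise_sd,
            missing_rate=config.proteome_missing_rate,
            rng=np.random.default_rng(keys[3]))
        truth.signature_up = up
        truth.signature_down = down
        cyto, cyto_status = generate_cytokines(
            sample_ids, rng=np.random.default_rng(keys[4]))
        counts, genes, scmeta, big_like = generate_scrna(
            n_patients=min(config.n_samples, 10),
            rng=np.random.default_rng(keys[5]))
        truth.big_like_cells = big_like
        clinical = generate_survival(config, truth)
    return Cohort(config, cells, layout, proteome, vbig, vsmall, cyto,
                  cyto_status, counts, genes, scmeta, clinical, truth)


# ---------------------------------------------------------------------------
# proteome


def generate_proteome(fraction_big: pd.Series, *, n_proteins: int = 2000,
                      n_signature: int = 100, effect: float = 0.8,
                      noise_sd: float = 1.0, missing_rate: float = 0.05,
                      validation_pairs: int = 4, validation_fc: float = 0.6,
                      validation_sd: float = 0.2,
                      drug_covariates: pd.DataFrame | None = None,
                      drug_effect: float = 0.8,
                      rng: np.random.Generator | int = 0,
                      ):
    """Proteins x samples raw abundance matrix with planted associations.

    Signature proteins (half up, half down) satisfy
    ``log10(abundance) = ±effect * z(fraction_big) + noise``; a matched
    big/small validation pair set carries a planted log2 fold change of
    ``±validation_fc``. Optional ``drug_covariates`` (samples x drugs)
    plants additional proteins covarying with drug sensitivity.

    Returns ``(raw, up, down, validation_big, validation_small)``.
    """
    if n_signature > n_proteins:
        raise ValueError("n_signature exceeds n_proteins")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    samples = list(fraction_big.index)
    fb = fraction_big.to_numpy(dtype=float)
    fb_z = (fb - fb.mean()) / (fb.std() if fb.std() > 0 else 1.0)

    names = [f"P{i:05d}" for i in range(n_proteins)]
    n_up = n_signature // 2
    up = names[:n_up]
    down = names[n_up:n_signature]

    z = noise_sd * rng.standard_normal((n_proteins, len(samples)))
    z[:n_up] += effect * fb_z
    z[n_up:n_signature] -= effect * fb_z

    extra = 0
    if drug_covariates is not None:
        for d, col in enumerate(drug_covariates.columns):
            v = drug_covariates[col].reindex(samples).to_numpy(dtype=float)
            vz = (v - np.nanmean(v)) / (np.nanstd(v) or 1.0)
            row = n_signature + extra
            if row >= n_proteins:
                break
            z[row] += drug_effect * np.nan_to_num(vz)
            extra += 1

    raw = pd.DataFrame(10.0 ** z, index=names, columns=samples)
    if missing_rate > 0:
        mask = rng.uniform(size=raw.shape) < missing_rate
        raw = raw.mask(mask)

    # paired big/small validation abundances, log2 scale
    delta = validation_sd * rng.standard_normal((n_proteins, validation_pairs))
    delta[:n_up] += validation_fc
    delta[n_up:n_signature] -= validation_fc
    base = rng.normal(10.0, 1.0, size=(n_proteins, validation_pairs))
    pairs = [f"V{i}" for i in range(validation_pairs)]
    vbig = pd.DataFrame(base + delta / 2, index=names, columns=pairs)
    vsmall = pd.DataFrame(base - delta / 2, index=names, columns=pairs)
    return raw, up, down, vbig, vsmall


def generate_validation_pairs(*args, **kwargs):
    raise NotImplementedError(
        "validation pairs are produced by generate_proteome")


# ---------------------------------------------------------------------------
# cytokines


def generate_cytokines(sample_ids: Sequence[str], *, n_cytokines: int = 64,
                       below_lod_rate: float = 0.05, above_max_rate: float = 0.02,
                       rng: np.random.Generator | int = 0):
    """Cytokines x samples concentration panel with detection statuses."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    names = [f"CK{i:02d}" for i in range(n_cytokines)]
    base = rng.normal(2.0, 0.8, size=(n_cytokines, 1))
    sample_scale = rng.normal(0.0, 0.3, size=(1, len(sample_ids)))
    conc = 10 ** (base + sample_scale
                  + 0.4 * rng.standard_normal((n_cytokines, len(sample_ids))))
    status = np.full(conc.shape, "ok", dtype=object)
    u = rng.uniform(size=conc.shape)
    status[u < below_lod_rate] = "below_lod"
    status[(u >= below_lod_rate) & (u < below_lod_rate + above_max_rate)] = "above_max"
    conc_df = pd.DataFrame(conc, index=names, columns=list(sample_ids))
    status_df = pd.DataFrame(status, index=names, columns=list(sample_ids))
    return conc_df, status_df


# ---------------------------------------------------------------------------
# scRNA


def generate_scrna(*, n_patients: int = 10, cells_per_patient: int = 120,
                   n_up: int = 20, n_down: int = 20, n_filler: int = 100,
                   n_ig: int = 10, n_mito: int = 10,
                   big_like_elevation: float = 5.0,
                   big_fraction_by_group: Mapping[str, float] | None = None,
                   n_low_umi: int = 0, n_high_mito: int = 0, n_marker_pos: int = 0,
                   rng: np.random.Generator | int = 0):
    """Genes x cells UMI counts emulating a myeloma plasma-cell dataset.

    Gene space = up/down signature genes, filler genes, immunoglobulin
    genes, mitochondrial genes and the lineage exclusion markers. A
    planted subset of cells is "big-like": its up-signature genes are
    elevated ``big_like_elevation``-fold. Optional planted QC violations
    (low UMI, high mito, exclusion-marker-positive) for filter testing.

    Returns ``(counts, gene_flags, cell_meta, big_like_truth)``.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    big_fraction_by_group = dict(big_fraction_by_group
                                 or {"relapse": 0.45, "refractory": 0.55})
    groups = list(big_fraction_by_group)

    up_genes = [f"BIGSIG{i}" for i in range(n_up)]
    down_genes = [f"SMALLSIG{i}" for i in range(n_down)]
    filler = [f"GENE{i}" for i in range(n_filler)]
    ig_genes = [f"IGHV{i}" for i in range(n_ig)]
    mito_genes = [f"MT-G{i}" for i in range(n_mito)]
    genes = (up_genes + down_genes + filler + ig_genes + mito_genes
             + list(_EXCLUSION_MARKERS))
    g = len(genes)

    base_rate = np.concatenate([
        np.full(n_up, 2.0), np.full(n_down, 2.0), np.full(n_filler, 1.0),
        np.full(n_ig, 5.0), np.full(n_mito, 1.5),
        np.zeros(len(_EXCLUSION_MARKERS)),
    ])

    cols, metas, big_truth = [], [], {}
    counts_cols = []
    for p in range(n_patients):
        pid = f"PT{p:02d}"
        group = groups[p % len(groups)]
        frac_big = big_fraction_by_group[group]
        for c in range(cells_per_patient):
            cid = f"{pid}_C{c:03d}"
            is_big = rng.uniform() < frac_big
            rate = base_rate.copy()
            if is_big:
                rate[:n_up] *= big_like_elevation
            else:
                rate[n_up:n_up + n_down] *= big_like_elevation
            counts_cols.append(rng.poisson(rate))
            cols.append(cid)
            metas.append((cid, pid, group))
            big_truth[cid] = bool(is_big)

    counts = pd.DataFrame(np.column_stack(counts_cols), index=genes, columns=cols)

    # planted QC violations on extra cells
    extra = []
    for i in range(n_low_umi):
        cid = f"QC_LOWUMI_{i}"
        vec = np.zeros(g, dtype=int)
        nz = rng.integers(0, 299)  # < 300 non-Ig UMIs
        vec[n_up + n_down:n_up + n_down + n_filler][:1] = nz
        extra.append((cid, vec))
    for i in range(n_high_mito):
        cid = f"QC_HIMITO_{i}"
        vec = np.zeros(g, dtype=int)
        vec[:n_up] = 10
        mito_slice = slice(n_up + n_down + n_filler + n_ig,
                           n_up + n_down + n_filler + n_ig + n_mito)
        vec[mito_slice] = 100  # mito fraction >> 0.5
        extra.append((cid, vec))
    for i in range(n_marker_pos):
        cid = f"QC_MARKER_{i}"
        vec = rng.poisson(base_rate)
        vec[-len(_EXCLUSION_MARKERS) + int(rng.integers(len(_EXCLUSION_MARKERS)))] = 1
        vec[:n_up] = 30  # plenty of UMIs so only the marker rule fires
        extra.append((cid, vec))
    if extra:
        extra_df = pd.DataFrame({cid: vec for cid, vec in extra}, index=genes)
        counts = pd.concat([counts, extra_df], axis=1)
        metas.extend((cid, "QC", "qc") for cid, _ in extra)

    gene_flags = pd.DataFrame({
        "is_immunoglobulin": [gname.startswith("IGHV") for gname in genes],
        "is_mitochondrial": [gname.startswith("MT-") for gname in genes],
        "is_exclusion_marker": [gname in _EXCLUSION_MARKERS for gname in genes],
    }, index=genes)
    cell_meta = pd.DataFrame(metas, columns=["cell_id", "patient_id", "group"]
                             ).set_index("cell_id")
    return counts, gene_flags, cell_meta, big_truth


# ---------------------------------------------------------------------------
# survival


def survival_times(ipcy: np.ndarray, hazard: HazardModel,
                   rng: np.random.Generator | int = 0,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with log-hazard linear in centered iPCY,
    under independent exponential censoring; returns (times, events)."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    ipcy = np.asarray(ipcy, dtype=float)
    rate = hazard.baseline_rate * np.exp(
        hazard.log_hr_coef * (ipcy - ipcy.mean()))
    t_event = rng.exponential(1.0 / rate)
    if hazard.censor_rate > 0:
        c_rate = hazard.baseline_rate * hazard.censor_rate / (
            1 - hazard.censor_rate)
        censor = rng.exponential(1.0 / c_rate, size=ipcy.size)
    else:
        censor = np.full(ipcy.size, np.inf)
    times = np.minimum(t_event, censor)
    events = (t_event <= censor).astype(int)
    return np.maximum(times, 1e-9), events


def generate_survival(config: CohortConfig, truth: GroundTruth,
                      regimens: Mapping[str, Sequence[str]] | None = None,
                      ) -> pd.DataFrame:
    """Clinical table with exponential event times whose log-hazard is
    linear in centered true iPCY; independent exponential censoring."""
    hm = config.hazard_model
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 777)))
    sample_ids = sorted(truth.phenogroup)
    panel = {t.name: t for t in config.drug_panel}

    if regimens is None:
        regimens = {}
        names = list(panel)
        for i, sid in enumerate(sample_ids):
            spec = panel[names[i % len(names)]]
            regimens[sid] = list(spec.components)

    rows = []
    ipcys = {}
    for i, sid in enumerate(sample_ids):
        regimen = set(regimens[sid])
        matched = [t for t in panel.values() if set(t.components) <= regimen]
        ipcys[sid] = sum(truth.expected_pcy[sid][t.name] for t in matched)
    center = np.mean(list(ipcys.values()))
    ipcy_vec = np.array([ipcys[sid] for sid in sample_ids])
    times, events = survival_times(ipcy_vec, hm, rng)
    for i, sid in enumerate(sample_ids):
        time, event = float(times[i]), int(events[i])
        immuno = any(panel[t].kind == "antibody" for t in
                     (t.name for t in panel.values()
                      if set(t.components) <= set(regimens[sid])))
        rows.append({
            "patient_id": sid, "sample_id": sid,
            "treatment_stage": f"MM:{i % 4}",
            "clonality": ("kappa", "lambda")[i % 2],
            "del17p": bool(i % 5 == 0), "t_11_14": bool(i % 7 == 0),
            "active_clonal": True,
            "subcohort": "immunotherapy" if immuno else "non_immunotherapy",
            "next_regimen": "+".join(sorted(regimens[sid])),
            "time_to_next_treatment_days": max(time, 1e-6),
            "event": event,
        })
        truth.hazard_group[sid] = ("sensitive" if ipcys[sid] > center
                                   else "resistant")
        truth.true_ipcy[sid] = float(ipcys[sid])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, str]:
    """Write every generated table as plain text; returns path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _w(name, fn):
        p = outdir / name
        fn(p)
        paths[name] = str(p)

    fmt = "%.6g"
    _w("cells.tsv", lambda p: cohort.cells.to_csv(
        p, sep="\t", index=False, float_format=fmt))
    _w("plate_layout.csv", lambda p: cohort.layout.to_csv(p, index=False))
    if cohort.proteome is not None:
        _w("proteome.tsv", lambda p: cohort.proteome.to_csv(
            p, sep="\t", float_format=fmt))
        _w("validation_big.tsv", lambda p: cohort.validation_big.to_csv(
            p, sep="\t", float_format=fmt))
        _w("validation_small.tsv", lambda p: cohort.validation_small.to_csv(
            p, sep="\t", float_format=fmt))
    if cohort.cytokines is not None:
        _w("cytokines.csv", lambda p: cohort.cytokines.to_csv(
            p, float_format=fmt))
        _w("cytokine_status.csv", lambda p: cohort.cytokine_status.to_csv(p))
    if cohort.scrna_counts is not None:
        sc_dir = outdir / "scrna"
        sc_dir.mkdir(exist_ok=True)
        from scipy import io as sio
        from scipy import sparse
        sio.mmwrite(str(sc_dir / "matrix.mtx"),
                    sparse.csr_matrix(cohort.scrna_counts.to_numpy()))
        cohort.scrna_genes.to_csv(sc_dir / "genes.tsv", sep="\t")
        cohort.scrna_cells.to_csv(sc_dir / "cells.tsv", sep="\t")
        paths["scrna"] = str(sc_dir)
    if cohort.clinical is not None:
        _w("clinical.csv", lambda p: cohort.clinical.to_csv(
            p, index=False, float_format=fmt))
    _w("ground_truth.json", lambda p: p.write_text(cohort.truth.to_json()))
    return paths
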