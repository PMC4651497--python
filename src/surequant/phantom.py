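"""Synthetic brain phantoms: template, individualized anatomies, lesions, cohorts.

The phantom is a desk-scale stand-in for a DTI study population. A template
brain is built from nested ellipsoids — an outer cortical gray-matter shell,
a white-matter interior, and central CSF ventricles — with tissue-specific
fractional-anisotropy (FA) distributions: each tissue voxel receives a frozen
"texture" value drawn from the tissue's mean ± sd, and every individual
acquisition adds fresh voxelwise measurement noise on top. Individuals are
the template warped by a random smooth deformation (the ground-truth field
is kept on the record), so the exact map between any two cohort members is
known and registration error can be injected in controlled amounts
downstream. Focal low-FA lesions of known extent provide detection ground
truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import DisplacementField, TissueSegmentation, Volume
from .registration import (
    apply_displacement,
    jacobian_determinant,
    random_smooth_field,
    resample_segmentation,
)

__all__ = [
    "TissueGeometry",
    "PhantomSpec",
    "LesionSpec",
    "SubjectRecord",
    "Cohort",
    "InvalidSpecError",
    "make_template_phantom",
    "sample_individual",
    "insert_lesion",
    "make_cohort",
    "load_cohort",
]

MANIFEST_COLUMNS = [
    "id", "role", "fa_path", "struct_path", "wm_path", "gm_path", "csf_path", "lesion_path",
]


class InvalidSpecError(ValueError):
    """Phantom specification violates a geometric or statistical invariant."""


@dataclass(frozen=True)
class TissueGeometry:
    """Nested-ellipsoid compartments, in voxel units.

    The brain is an ellipsoid of ``brain_radii_vox``; its outer shell of
    ``shell_thickness_vox`` is cortical GM; the interior is WM except for two
    CSF ventricles (ellipsoids of ``ventricle_radii_vox`` offset by
    ``±ventricle_offset_vox`` along the first axis).
    """

    brain_radii_vox: tuple[float, float, float] = (25.0, 28.0, 25.0)
    shell_thickness_vox: float = 3.0
    ventricle_radii_vox: tuple[float, float, float] = (4.0, 9.0, 4.0)
    ventricle_offset_vox: float = 5.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cohort generator.

    ``fa_params`` maps tissue -> (mean, sd) of the frozen FA texture
    (unitless, in [0,1]); ``noise_sd`` is the fresh per-acquisition voxel
    noise. ``variability_amplitude_mm`` is the RMS magnitude of the random
    smooth deformation that individualizes each brain and
    ``variability_smoothness_mm`` its Gaussian correlation scale.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    tissue_geometry: TissueGeometry = field(default_factory=TissueGeometry)
    fa_params: dict = field(
        default_factory=lambda: {
            "wm": (0.50, 0.05),
            "gm": (0.15, 0.03),
            "csf": (0.05, 0.02),
        }
    )
    noise_sd: float = 0.02
    variability_amplitude_mm: float = 2.0
    variability_smoothness_mm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if any(int(n) <= 0 for n in self.grid_shape):
            raise InvalidSpecError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise InvalidSpecError("voxel_size_mm must be > 0")
        for tissue in ("wm", "gm", "csf"):
            if tissue not in self.fa_params:
                raise InvalidSpecError(f"fa_params missing tissue {tissue!r}")
            mean, sd = self.fa_params[tissue]
            if not (0.0 <= mean <= 1.0) or sd < 0:
                raise InvalidSpecError(
                    f"FA mean for {tissue} must be in [0,1] with sd >= 0, got {mean}±{sd}"
                )
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.variability_amplitude_mm < 0:
            raise InvalidSpecError("variability_amplitude_mm must be >= 0")
        if self.variability_smoothness_mm <= 0:
            raise InvalidSpecError("variability_smoothness_mm must be > 0")
        g = self.tissue_geometry
        if g.shell_thickness_vox >= min(g.brain_radii_vox):
            raise InvalidSpecError(
                "degenerate geometry: cortical shell thickness "
                f"{g.shell_thickness_vox} >= smallest brain radius "
                f"{min(g.brain_radii_vox)}"
            )
        inner = tuple(r - g.shell_thickness_vox for r in g.brain_radii_vox)
        if g.ventricle_offset_vox + g.ventricle_radii_vox[0] >= inner[0] or any(
            vr >= ir for vr, ir in zip(g.ventricle_radii_vox, inner)
        ):
            raise InvalidSpecError(
                "ventricles must nest strictly inside the white-matter interior"
            )

    # YAML-style config round trip ------------------------------------
    def to_yaml(self, path) -> None:
        def listify(obj):
            if isinstance(obj, tuple):
                return [listify(o) for o in obj]
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            return obj

        d = dataclasses.asdict(self)
        d["tissue_geometry"] = dataclasses.asdict(self.tissue_geometry)
        Path(path).write_text(yaml.safe_dump(listify(d), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        if "tissue_geometry" in d:
            geo = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in d["tissue_geometry"].items()}
            d["tissue_geometry"] = TissueGeometry(**geo)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "fa_params" in d:
            d["fa_params"] = {k: tuple(v) for k, v in d["fa_params"].items()}
        return cls(**d)


@dataclass(frozen=True)
class LesionSpec:
    """A spherical focal FA reduction inside white matter."""

    center: tuple[int, int, int]
    radius_mm: float
    fa_delta: float

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise InvalidSpecError("lesion radius_mm must be > 0")
        if not (0.0 < self.fa_delta <= 1.0):
            raise InvalidSpecError("lesion fa_delta must be in (0, 1]")


@dataclass(frozen=True, eq=False)
class SubjectRecord:
    """One individual's images, segmentation, and phantom ground truth.

    ``truth_field`` is the deformation that produced this individual from
    the template (zero for the template itself, absent for records derived
    by registration); ``fa_clean`` is the noise-free FA texture underlying
    ``fa`` (phantom ground truth, absent for derived records);
    ``lesion_mask`` marks ground-truth lesion voxels when present.
    """

    id: str
    fa: Volume
    structural: Volume
    seg: TissueSegmentation
    truth_field: DisplacementField | None = None
    lesion_mask: Volume | None = None
    fa_clean: Volume | None = None

    def __post_init__(self):
        self.fa.require_same_grid(self.structural, "record volumes")
        self.fa.require_same_grid(self.seg.wm, "record volumes")
        brain = self.seg.brain.data.astype(bool)
        inside = self.fa.data[brain]
        if inside.size and (inside.min() < -1e-9 or inside.max() > 1 + 1e-9):
            raise ValueError("FA must lie in [0,1] inside the brain mask")
        if self.lesion_mask is not None:
            self.fa.require_same_grid(self.lesion_mask, "record volumes")
            if (
                self.lesion_mask.data.astype(bool)
                & ~self.seg.wm.data.astype(bool)
            ).any():
                raise ValueError("lesion_mask must lie inside the WM mask")


def _ellipsoid(shape, center, radii):
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


STRUCT_INTENSITY = {"wm": 100.0, "gm": 60.0, "csf": 20.0}


def make_template_phantom(spec: PhantomSpec) -> SubjectRecord:
    """Build the template brain: masks, FA texture, structural contrast.

    Deterministic given ``spec.seed``. The template's ``truth_field`` is the
    zero field (it is its own anatomy).
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    center = tuple((n - 1) / 2.0 for n in shape)
    g = spec.tissue_geometry
    brain = _ellipsoid(shape, center, g.brain_radii_vox)
    inner = _ellipsoid(
        shape, center, tuple(r - g.shell_thickness_vox for r in g.brain_radii_vox)
    )
    vent = np.zeros(shape, dtype=bool)
    for sgn in (-1.0, 1.0):
        c = (center[0] + sgn * g.ventricle_offset_vox, center[1], center[2])
        vent |= _ellipsoid(shape, c, g.ventricle_radii_vox)
    vent &= inner
    gm = brain & ~inner
    wm = inner & ~vent
    csf = vent

    rng = np.random.default_rng(spec.seed)
    vs = (spec.voxel_size_mm,) * 3
    fa_clean = np.zeros(shape, dtype=np.float32)
    struct = np.zeros(shape, dtype=np.float32)
    for name, mask in (("wm", wm), ("gm", gm), ("csf", csf)):
        mean, sd = spec.fa_params[name]
        fa_clean[mask] = np.clip(mean + sd * rng.standard_normal(int(mask.sum()), dtype=np.float32), 0, 1)
        struct[mask] = STRUCT_INTENSITY[name]
    fa = fa_clean.copy()
    fa[brain] = np.clip(
        fa[brain] + spec.noise_sd * rng.standard_normal(int(brain.sum()), dtype=np.float32), 0, 1
    )

    as_vol = lambda a: Volume(a, voxel_size_mm=vs)
    seg = TissueSegmentation(
        as_vol(wm.astype(np.uint8)), as_vol(gm.astype(np.uint8)), as_vol(csf.astype(np.uint8))
    )
    fa_vol = as_vol(fa)
    return SubjectRecord(
        id="template",
        fa=fa_vol,
        structural=as_vol(struct),
        seg=seg,
        truth_field=DisplacementField.zero(fa_vol),
        fa_clean=as_vol(fa_clean),
    )


def sample_individual(
    template: SubjectRecord, spec: PhantomSpec, seed: int | np.random.Generator,
    id: str = "individual",
) -> SubjectRecord:
    """Warp the template by a random smooth deformation and re-noise the FA.

    The generating field is recorded as ``truth_field``; masks are resampled
    nearest-neighbour under the same deformation, the FA texture linearly,
    and fresh voxel noise is added inside the warped brain. Raises if the
    deformation folds the grid (non-positive Jacobian).
    """
    if template.fa_clean is None or template.truth_field is None:
        raise ValueError("template must come from make_template_phantom")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = random_smooth_field(
        template.fa,
        spec.variability_amplitude_mm,
        spec.variability_smoothness_mm,
        rng,
    )
    if not u.is_zero():
        jmin = float(jacobian_determinant(u).min())
        if jmin <= 0:
            raise InvalidSpecError(
                f"variability_amplitude_mm={spec.variability_amplitude_mm} folds "
                f"the grid (min Jacobian {jmin:.3f}); reduce the amplitude or "
                "increase the smoothness"
            )
    seg = resample_segmentation(template.seg, u)
    fa_clean = apply_displacement(template.fa_clean, u, "linear", fill=0.0)
    struct = apply_displacement(template.structural, u, "linear", fill=0.0)
    brain = seg.brain.data.astype(bool)
    fa = fa_clean.data.copy()
    fa[brain] = np.clip(
        fa[brain] + spec.noise_sd * rng.standard_normal(int(brain.sum()), dtype=np.float32), 0, 1
    )
    fa = np.clip(fa, 0, 1)
    return SubjectRecord(
        id=id,
        fa=fa_clean.with_data(fa),
        structural=struct,
        seg=seg,
        truth_field=u,
        fa_clean=fa_clean,
    )


def insert_lesion(record: SubjectRecord, lesion: LesionSpec) -> SubjectRecord:
    """Subtract ``fa_delta`` from FA inside (sphere ∩ WM); record the mask.

    The lesion is clipped to white matter (low-FA ground truth is only
    meaningful where the analysis looks); an entirely extra-WM sphere is an
    error.
    """
    shape = record.fa.shape
    vs = record.fa.voxel_size_mm
    radii_vox = tuple(lesion.radius_mm / s for s in vs)
    sphere = _ellipsoid(shape, lesion.center, radii_vox)
    mask = sphere & record.seg.wm.data.astype(bool)
    if not mask.any():
        raise InvalidSpecError(
            f"lesion sphere at {lesion.center} (r={lesion.radius_mm} mm) does "
            "not intersect white matter"
        )
    fa = record.fa.data.copy()
    fa[mask] = np.clip(fa[mask] - lesion.fa_delta, 0, 1)
    prior = record.lesion_mask.data.astype(bool) if record.lesion_mask is not None else 0
    return dataclasses.replace(
        record,
        fa=record.fa.with_data(fa),
        lesion_mask=record.fa.with_data((mask | prior).astype(np.uint8)),
    )


@dataclass(frozen=True, eq=False)
class Cohort:
    """A template plus control and subject records from one generator run."""

    template: SubjectRecord
    controls: tuple[SubjectRecord, ...]
    subjects: tuple[SubjectRecord, ...]
    spec: PhantomSpec
    seed: int

    @property
    def all_records(self):
        return (self.template, *self.controls, *self.subjects)


def make_cohort(
    spec: PhantomSpec,
    n_controls: int,
    subjects: list[LesionSpec | None],
    seed: int,
    out_dir=None,
) -> Cohort:
    """Generate a full cohort: template, controls, and (lesioned) subjects.

    Child seeds are spawned deterministically from ``seed``. When ``out_dir``
    is given, every volume is written as NIfTI and a TSV manifest
    (``manifest.tsv``) with one row per record is produced.
    """
    if n_controls < 2:
        raise InvalidSpecError("n_controls must be >= 2 (group variance undefined)")
    template = make_template_phantom(
        dataclasses.replace(spec, seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)))
    )
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_controls + len(subjects))

    def sample_valid(child, rec_id):
        # The Gaussian deformation model has unbounded tails, so a draw can
        # occasionally fold the grid; reject and redraw deterministically.
        grandchildren = child.spawn(20)
        for gc in grandchildren:
            try:
                return sample_individual(template, spec, np.random.default_rng(gc), id=rec_id)
            except InvalidSpecError:
                continue
        raise InvalidSpecError(
            f"could not draw a non-folding deformation for {rec_id} in 20 "
            f"attempts; variability_amplitude_mm={spec.variability_amplitude_mm} "
            "is too large for the chosen smoothness"
        )

    controls = tuple(
        sample_valid(children[i], f"CTRL{i + 1:02d}") for i in range(n_controls)
    )
    subj_records = []
    for j, lesion in enumerate(subjects):
        rec = sample_valid(children[n_controls + j], f"SUBJ{j + 1:02d}")
        if lesion is not None:
            rec = insert_lesion(rec, lesion)
        subj_records.append(rec)
    cohort = Cohort(template, controls, tuple(subj_records), spec, seed)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def _record_role(cohort: Cohort, rec: SubjectRecord) -> str:
    if rec is cohort.template:
        return "template"
    return "control" if rec in cohort.controls else "subject"


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write all cohort volumes as NIfTI plus a TSV manifest; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.all_records:
        paths = {key: f"{rec.id}_{key}.nii.gz" for key in ("fa", "struct", "wm", "gm", "csf")}
        rec.fa.save(out / paths["fa"])
        rec.structural.save(out / paths["struct"])
        rec.seg.save(out / paths["wm"], out / paths["gm"], out / paths["csf"])
        lesion_path = "-"
        if rec.lesion_mask is not None:
            lesion_path = f"{rec.id}_lesion.nii.gz"
            rec.lesion_mask.save(out / lesion_path)
        rows.append(
            dict(
                id=rec.id,
                role=_record_role(cohort, rec),
                fa_path=paths["fa"],
                struct_path=paths["struct"],
                wm_path=paths["wm"],
                gm_path=paths["gm"],
                csf_path=paths["csf"],
                lesion_path=lesion_path,
            )
        )
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_cohort(manifest_path) -> tuple[SubjectRecord, list[SubjectRecord], list[SubjectRecord]]:
    """Read a manifest back into (template, controls, subjects) records.

    Truth fields are not serialized, so reloaded records support the
    voxelwise/misregistration stages but not simulated registration.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t")
    template, controls, subjects = None, [], []
    for _, row in df.iterrows():
        lesion = None
        if row["lesion_path"] != "-":
            v = Volume.load(base / row["lesion_path"])
            lesion = v.with_data((np.asarray(v.data) > 0.5).astype(np.uint8))
        rec = SubjectRecord(
            id=row["id"],
            fa=Volume.load(base / row["fa_path"]),
            structural=Volume.load(base / row["struct_path"]),
            seg=TissueSegmentation.load(
                base / row["wm_path"], base / row["gm_path"], base / row["csf_path"]
            ),
            lesion_mask=lesion,
        )
        if row["role"] == "template":
            template = rec
        elif row["role"] == "control":
            controls.append(rec)
        else:
            subjects.append(rec)
    return template, controls, subjects
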