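"""Nonlinear spatial transforms and simulated imperfect registration.

Deformable registration of one brain onto another is treated as an upstream
black box: in a phantom cohort every individual carries the ground-truth
deformation that generated it from the template, so the exact moving-to-target
map is known analytically (``exact_map``) and an *imperfect* registration is
modelled as that exact map composed with a fresh random smooth residual field
of controlled amplitude (``simulate_registration``). This is the controlled
stand-in for the residual error that any real registration algorithm leaves
behind, and it is the quantity whose downstream consequences (misregistration
of GM/CSF onto template WM, spurious low-FA clusters) the package measures.

Real registration engines can be plugged in by supplying the recovered
DisplacementField directly; none is implemented here.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .grid import DisplacementField, GridMismatchError, Volume

__all__ = [
    "apply_displacement",
    "resample_segmentation",
    "compose",
    "invert",
    "random_smooth_field",
    "jacobian_determinant",
    "exact_map",
    "simulate_registration",
    "track_voxel",
    "TrackedVoxel",
    "InversionError",
]


class InversionError(RuntimeError):
    """Fixed-point inversion failed to reach the requested tolerance."""


def _index_grid(shape):
    return np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")


def _sample_coords(field: DisplacementField):
    """Voxel coordinates each output voxel samples from: v + d(v)/spacing."""
    idx = _index_grid(field.shape)
    vs = field.grid.voxel_size_mm
    return [idx[a] + field.vectors[..., a] / vs[a] for a in range(3)]


def apply_displacement(
    vol: Volume,
    field: DisplacementField,
    interpolation: str = "linear",
    fill: float = 0.0,
    is_mask: bool = False,
) -> Volume:
    """Resample ``vol`` through ``field`` (pull convention).

    The output voxel at index ``v`` takes the input value at
    ``v + d(v)/spacing``; samples falling outside the input domain take
    ``fill``. Binary masks must be resampled with nearest-neighbour
    interpolation (``is_mask=True`` enforces this, protecting tissue-mask
    binarity and disjointness).
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    if is_mask and interpolation == "linear":
        raise ValueError("binary masks must use nearest-neighbour interpolation")
    if vol.shape != field.shape:
        raise GridMismatchError(f"volume grid {vol.shape} != field grid {field.shape}")
    # keep the input's float precision; promote ints/bools to float32
    work_dtype = vol.data.dtype if vol.data.dtype.kind == "f" else np.float32
    if field.is_zero():
        # identity: exact for nearest and (bar float round-trip) for linear
        data = (
            vol.data.copy()
            if interpolation == "nearest"
            else vol.data.astype(work_dtype, copy=True)
        )
        return vol.with_data(data)
    order = 1 if interpolation == "linear" else 0
    out = map_coordinates(
        np.asarray(vol.data, dtype=work_dtype),
        _sample_coords(field),
        order=order,
        mode="constant",
        cval=fill,
    )
    if is_mask:
        out = out.astype(vol.data.dtype)
    return vol.with_data(out)


def resample_segmentation(seg, field: DisplacementField, fill: float = 0.0):
    """Resample all three tissue masks with nearest-neighbour interpolation.

    Nearest sampling pulls every mask from the same source voxel, so the
    resampled masks remain binary and pairwise disjoint by construction.
    """
    from .grid import TissueSegmentation

    return TissueSegmentation(
        *(
            apply_displacement(m, field, "nearest", fill=fill, is_mask=True)
            for m in (seg.wm, seg.gm, seg.csf)
        )
    )


def _sample_field(field: DisplacementField, coords) -> np.ndarray:
    """Linearly interpolate the vector field at continuous voxel coords.

    Edge handling is 'nearest' (clamp), not constant fill: a smooth field
    extended by clamping stays smooth, which compose/invert rely on.
    """
    out = np.empty(coords[0].shape + (3,), dtype=np.float32)
    for a in range(3):
        out[..., a] = map_coordinates(
            field.vectors[..., a], coords, order=1, mode="nearest"
        )
    return out


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Field ``c`` with ``apply(c, V) == apply(outer, apply(inner, V))``.

    In the pull convention ``c(v) = outer(v) + inner(v + outer(v))``, the
    inner field being linearly interpolated off-grid.
    """
    if outer.shape != inner.shape:
        raise GridMismatchError(f"field grids differ: {outer.shape} vs {inner.shape}")
    if outer.is_zero():
        return inner  # fields are immutable; sharing is safe
    if inner.is_zero():
        return outer
    vec = outer.vectors + _sample_field(inner, _sample_coords(outer))
    return DisplacementField(vec, outer.grid)


def invert(
    field: DisplacementField, tol: float = 0.05, max_iter: int = 50,
    relaxation: float = 0.5, mask: np.ndarray | None = None,
) -> DisplacementField:
    """Fixed-point inverse: find g with ``compose(field, g)`` ≈ zero.

    Under-relaxed Picard iteration ``g <- (1-ω)·g − ω·field(v + g(v))``
    (ω = ``relaxation``); the damping keeps the iteration contractive for
    fields whose local gradients approach one voxel per voxel, where the
    plain iteration oscillates. ``tol`` is the maximum residual displacement
    of the composition, in voxel units, checked inside ``mask`` when given
    (e.g. a brain mask: near the grid boundary the true preimage may lie
    off-grid, where no discrete inverse can drive the residual to zero).
    Raises InversionError (reporting the residual) if the tolerance cannot
    be reached — either the field folds or its roughness exceeds what
    trilinear field interpolation can represent at ``tol``.
    """
    if field.is_zero():
        return field  # its own inverse; fields are immutable
    if not (0.0 < relaxation <= 1.0):
        raise ValueError("relaxation must be in (0, 1]")
    min_vs = min(field.grid.voxel_size_mm)

    def residual(g):
        mag = compose(field, g).magnitude_mm()
        if mask is not None:
            mag = mag[mask]
        return float(mag.max()) / min_vs

    inv = DisplacementField(-field.vectors, field.grid)
    for _ in range(max_iter):
        err = residual(inv)
        if err < tol:
            return inv
        update = -_sample_field(field, _sample_coords(inv))
        inv = DisplacementField(
            (1.0 - relaxation) * inv.vectors + relaxation * update, field.grid
        )
    err = residual(inv)
    if err < tol:
        return inv
    raise InversionError(
        f"field inversion did not reach tol={tol} voxels in {max_iter} "
        f"iterations (residual {err:.3f} voxels)"
    )


def random_smooth_field(
    like: Volume,
    amplitude_mm: float,
    smoothness_mm: float,
    rng: np.random.Generator,
) -> DisplacementField:
    """Random smooth field with RMS displacement magnitude ``amplitude_mm``.

    I.i.d. Gaussian vector noise is smoothed component-wise by a Gaussian
    kernel of width ``smoothness_mm`` and rescaled so the grid-wide RMS of
    the displacement magnitude equals the requested amplitude.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    if smoothness_mm <= 0:
        raise ValueError("smoothness_mm must be > 0")
    if amplitude_mm == 0:
        return DisplacementField.zero(like)
    sigma_vox = [smoothness_mm / s for s in like.voxel_size_mm]
    vec = rng.standard_normal(like.shape + (3,), dtype=np.float32)
    for a in range(3):
        vec[..., a] = gaussian_filter(vec[..., a], sigma_vox)
    rms = np.sqrt((vec**2).sum(axis=-1).mean())
    vec *= amplitude_mm / rms
    return DisplacementField(vec, like)


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """Voxelwise Jacobian determinant of the mapping v -> v + d(v)/spacing.

    Values <= 0 indicate grid folding (the deformation is not invertible).
    """
    vs = field.grid.voxel_size_mm
    J = np.empty(field.shape + (3, 3))
    for comp in range(3):
        grads = np.gradient(field.vectors[..., comp] / vs[comp])
        for axis in range(3):
            J[..., comp, axis] = grads[axis] + (1.0 if comp == axis else 0.0)
    return np.linalg.det(J)


def exact_map(
    moving_truth: DisplacementField,
    target_truth: DisplacementField,
    **invert_kwargs,
) -> DisplacementField:
    """Exact moving-to-target map from known template-to-individual truths.

    With individuals generated as ``I = apply(u_I, T)`` from the template T,
    the field carrying the moving image onto the target anatomy is
    ``compose(u_target, invert(u_moving))``. Keyword arguments are passed to
    :func:`invert` (tolerance, iteration cap, convergence mask).
    """
    return compose(target_truth, invert(moving_truth, **invert_kwargs))


def simulate_registration(
    moving,
    target,
    residual_amplitude_mm: float = 0.0,
    residual_smoothness_mm: float = 6.0,
    seed: int | np.random.Generator = 0,
    precomputed_exact: DisplacementField | None = None,
):
    """Register ``moving`` onto ``target`` with controlled residual error.

    Returns ``(registered, recovered)`` where ``recovered`` is the exact
    truth-derived map composed with a fresh random smooth residual of the
    stated amplitude, and ``registered`` is the moving record resampled by
    it (FA and structural linearly, tissue masks nearest-neighbour). With
    ``residual_amplitude_mm = 0`` the exact map is reproduced.

    Both records must carry phantom truth fields; to use a real registration
    engine, compute its displacement field externally and resample with
    :func:`apply_displacement` directly.
    """
    if moving.truth_field is None or target.truth_field is None:
        raise ValueError(
            "simulate_registration needs phantom truth fields on both records; "
            "for real data supply a displacement field from an external "
            "registration engine and resample with apply_displacement"
        )
    exact = precomputed_exact
    if exact is None:
        # convergence of the truth-field inverse only matters where brain
        # content lives; near the grid boundary the preimage can be off-grid
        from scipy.ndimage import binary_dilation

        brain = binary_dilation(moving.seg.brain.data.astype(bool), iterations=2)
        exact = exact_map(
            moving.truth_field, target.truth_field,
            tol=0.1, max_iter=100, mask=brain,
        )
    if residual_amplitude_mm > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        residual = random_smooth_field(
            target.fa, residual_amplitude_mm, residual_smoothness_mm, rng
        )
        recovered = compose(exact, residual)
    else:
        recovered = exact
    fa_reg = apply_displacement(moving.fa, recovered, "linear", fill=0.0)
    registered = replace(
        moving,
        fa=fa_reg.with_data(np.clip(fa_reg.data, 0.0, 1.0)),
        structural=apply_displacement(moving.structural, recovered, "linear", fill=0.0),
        seg=resample_segmentation(moving.seg, recovered),
        lesion_mask=(
            None
            if moving.lesion_mask is None
            else apply_displacement(moving.lesion_mask, recovered, "nearest", is_mask=True)
        ),
        truth_field=None,
    )
    return registered, recovered


class TrackedVoxel:
    """Result of pushing one labelled voxel through a transform."""

    __slots__ = ("source", "continuous", "index", "in_domain")

    def __init__(self, source, continuous, index, in_domain):
        self.source = tuple(int(i) for i in source)
        self.continuous = tuple(float(c) for c in continuous)
        self.index = tuple(int(i) for i in index)
        self.in_domain = bool(in_domain)

    def __repr__(self):
        flag = "" if self.in_domain else ", out-of-domain"
        return f"TrackedVoxel({self.source} -> {self.continuous}{flag})"


def track_voxel(voxel, field: DisplacementField) -> TrackedVoxel:
    """Map a labelled voxel to its location under the transform.

    In the pull convention the output voxel ``v`` shows the input at
    ``v + d(v)/spacing``; tracking answers "which input location does this
    output voxel display", i.e. where a label placed at ``voxel`` on the
    output grid originates. Returns continuous voxel coordinates, the
    nearest voxel index, and whether the location falls inside the grid.
    """
    v = np.asarray(voxel, dtype=float)
    if v.shape != (3,):
        raise ValueError("voxel must be a 3-vector of indices")
    idx = tuple(int(round(c)) for c in v)
    if not all(0 <= idx[a] < field.shape[a] for a in range(3)):
        raise ValueError(f"voxel {idx} outside grid {field.shape}")
    d = field.vectors[idx]
    cont = v + d / np.asarray(field.grid.voxel_size_mm)
    nearest = np.rint(cont).astype(int)
    inside = all(0 <= nearest[a] < field.shape[a] for a in range(3))
    return TrackedVoxel(idx, cont, nearest, inside)
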