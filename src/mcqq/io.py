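"""File I/O, real-data compensation arithmetic, and run plumbing.

Volumes travel as NIfTI-1; complex echo stacks as paired 4-D files in one of
two dialects (magnitude+phase, the clinical-export default, or
real+imaginary), declared in a JSON sidecar together with echo times, units
and seeds.  Run configurations are YAML; metric reports are JSON and CSV.
Internal arrays are (x, y, z) in voxel space with the NIfTI affine handled
only at the I/O boundary and never silently resampled.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import nibabel as nib
import numpy as np
import yaml

from .biophysics import AcquisitionParams, ComplexSignalStack, ParameterMaps

__all__ = [
    "PhaseFieldInputs",
    "RunConfig",
    "compensate_phase",
    "compensate_magnitude",
    "read_nifti",
    "write_nifti",
    "read_signal_stack",
    "write_signal_stack",
    "read_parameter_maps",
    "write_parameter_maps",
    "read_run_config",
    "write_run_config",
    "write_metrics",
    "save_checkpoint",
    "load_checkpoint",
    "file_sha256",
    "log_stage",
]

logger = logging.getLogger("mcqq")

FIELD_UNITS = ("rad/s", "Hz")


# ---------------------------------------------------------------------------
# real-data signal preparation (compensation arithmetic)


@dataclass
class PhaseFieldInputs:
    """Wrapped echo phases plus unwrapped total/background fields.

    ``total_field`` and ``background_field`` share ``field_unit`` ("rad/s"
    or "Hz"); ``phi0`` is the echo-independent initial phase in radians
    (scalar or map).  All volumes must be co-registered on one grid.
    """

    wrapped_phase: np.ndarray      # (n_echo, x, y, z), radians in (-pi, pi]
    total_field: np.ndarray        # unwrapped fT
    background_field: np.ndarray   # unwrapped fB
    phi0: np.ndarray | float
    echo_times: tuple
    field_unit: str = "rad/s"

    def __post_init__(self) -> None:
        self.wrapped_phase = np.asarray(self.wrapped_phase, dtype=float)
        self.total_field = np.asarray(self.total_field, dtype=float)
        self.background_field = np.asarray(self.background_field, dtype=float)
        if self.field_unit not in FIELD_UNITS:
            raise ValueError(f"field_unit must be one of {FIELD_UNITS}")
        grid = self.wrapped_phase.shape[1:]
        for name in ("total_field", "background_field"):
            if getattr(self, name).shape != grid:
                raise ValueError(f"{name} grid does not match wrapped_phase")
        te = np.asarray(self.echo_times, dtype=float)
        if te.ndim != 1 or len(te) != self.wrapped_phase.shape[0]:
            raise ValueError("echo_times must match the phase echo axis")

    def fields_rad_s(self):
        f = 2.0 * np.pi if self.field_unit == "Hz" else 1.0
        return self.total_field * f, self.background_field * f


def compensate_phase(inputs: PhaseFieldInputs) -> np.ndarray:
    """Per-echo tissue phase phi' from wrapped phases and unwrapped fields.

    The wrapped phase is first unwrapped against the total-field prediction,
    ang_uw = ang - round((ang - fT*t - phi0) / 2pi) * 2pi, then the
    background field and initial phase are compensated:
    phi' = ang_uw - fB*t - phi0.  Adding any multiple of 2pi to the wrapped
    input leaves phi' unchanged.
    """
    ft, fb = inputs.fields_rad_s()
    te = np.asarray(inputs.echo_times, dtype=float)[:, None, None, None]
    ang = inputs.wrapped_phase
    pred = ft[None] * te + inputs.phi0
    ang_uw = ang - np.round((ang - pred) / (2.0 * np.pi)) * 2.0 * np.pi
    out = ang_uw - fb[None] * te - inputs.phi0
    if not np.all(np.isfinite(out)):
        raise ValueError("compensated phase contains non-finite values")
    return out


def compensate_magnitude(magnitudes: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Macroscopic-field compensation |S'| = |s| / G with G in (0, 1]."""
    magnitudes = np.asarray(magnitudes, dtype=float)
    G = np.asarray(G, dtype=float)
    if np.any(G <= 0) or np.any(G > 1):
        raise ValueError("G must lie in (0, 1]")
    return magnitudes / G


# ---------------------------------------------------------------------------
# NIfTI volumes


def write_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write an (x, y, z) or channel-leading 4-D array as NIfTI-1.

    A leading channel/echo axis is stored as the NIfTI 4th dimension so that
    spatial axes keep their geometric meaning.
    """
    data = np.asarray(data)
    if affine is None:
        affine = np.eye(4)
    if data.ndim == 4:
        data = np.moveaxis(data, 0, -1)
    elif data.ndim != 3:
        raise ValueError("expected a 3-D volume or a 4-D channel-leading stack")
    img = nib.Nifti1Image(np.ascontiguousarray(data.astype(np.float64)), affine)
    nib.save(img, str(path))


def read_nifti(path):
    """Read a NIfTI file -> (array, affine); 4-D data returns channel-leading."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4:
        data = np.moveaxis(data, -1, 0)
    return data, img.affine


def _check_affines(a, b, what):
    if not np.allclose(a, b, atol=1e-6):
        raise ValueError(f"inconsistent affines between {what}; "
                         "geometry is never silently resampled")


def write_signal_stack(prefix, signal: ComplexSignalStack,
                       dialect: str = "mag_phase",
                       affine: np.ndarray | None = None,
                       extra_meta: dict | None = None) -> dict:
    """Write a complex echo stack as two NIfTI files plus a JSON sidecar.

    ``dialect`` is "mag_phase" (default) or "real_imag"; the two component
    files are ``<prefix>_<comp>.nii`` and the sidecar ``<prefix>.json``
    records dialect, echo times (s), geometry and any extra provenance.
    """
    if dialect == "mag_phase":
        comps = {"mag": np.abs(signal.data), "phase": np.angle(signal.data)}
    elif dialect == "real_imag":
        comps = {"real": signal.data.real, "imag": signal.data.imag}
    else:
        raise ValueError("dialect must be 'mag_phase' or 'real_imag'")
    prefix = str(prefix)
    paths = {}
    for comp, arr in comps.items():
        p = f"{prefix}_{comp}.nii"
        write_nifti(p, arr, affine)
        paths[comp] = p
    meta = {
        "dialect": dialect,
        "n_echo": signal.n_echo,
        "echo_times_s": [float(t) for t in signal.acq.echo_times],
        "B0_T": signal.acq.B0,
        "B0_dir": [float(x) for x in signal.acq.B0_dir],
        "voxel_size_mm": [float(x) for x in signal.acq.voxel_size],
        "grid_shape": list(signal.data.shape[1:]),
        "files": {k: str(v) for k, v in paths.items()},
    }
    meta.update(extra_meta or {})
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return meta


def read_signal_stack(prefix) -> ComplexSignalStack:
    """Read a complex echo stack written by :func:`write_signal_stack`.

    Both dialects load to identical complex data; echo-count mismatches
    between the sidecar and the volumes are errors.
    """
    prefix = str(prefix)
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    comps, affines = {}, []
    for comp, path in meta["files"].items():
        arr, aff = read_nifti(path)
        comps[comp] = arr
        affines.append(aff)
    _check_affines(affines[0], affines[1], "echo-stack components")
    if meta["dialect"] == "mag_phase":
        data = comps["mag"] * np.exp(1j * comps["phase"])
    else:
        data = comps["real"] + 1j * comps["imag"]
    if data.shape[0] != meta["n_echo"]:
        raise ValueError(f"echo axis {data.shape[0]} does not match sidecar "
                         f"n_echo {meta['n_echo']}")
    acq = AcquisitionParams(echo_times=tuple(meta["echo_times_s"]),
                            B0=meta["B0_T"], B0_dir=tuple(meta["B0_dir"]),
                            voxel_size=tuple(meta["voxel_size_mm"]),
                            grid_shape=tuple(meta["grid_shape"]))
    return ComplexSignalStack(data, acq)


def write_parameter_maps(prefix, params: ParameterMaps,
                         affine: np.ndarray | None = None,
                         extra_meta: dict | None = None) -> None:
    """Write the five parameter maps (4-D NIfTI), mask, and a JSON sidecar."""
    prefix = str(prefix)
    write_nifti(f"{prefix}_maps.nii", params.stack(), affine)
    write_nifti(f"{prefix}_mask.nii", params.mask.astype(np.float64), affine)
    meta = {"parameters": list(ParameterMaps.PARAM_NAMES),
            "grid_shape": list(params.grid_shape)}
    meta.update(extra_meta or {})
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def read_parameter_maps(prefix) -> ParameterMaps:
    prefix = str(prefix)
    arr, aff_a = read_nifti(f"{prefix}_maps.nii")
    mask, aff_b = read_nifti(f"{prefix}_mask.nii")
    _check_affines(aff_a, aff_b, "parameter maps and mask")
    return ParameterMaps.from_stack(arr, mask > 0.5)


# ---------------------------------------------------------------------------
# run configuration, metrics, checkpoints, logging


@dataclass
class RunConfig:
    """Resolved, fully serializable description of one pipeline run."""

    command: str = ""
    seed: int = 0
    options: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    package_version: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_run_config(path, cfg: RunConfig) -> None:
    with open(str(path), "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def read_run_config(path) -> RunConfig:
    with open(str(path)) as fh:
        return RunConfig(**yaml.safe_load(fh))


def write_metrics(prefix, metrics: dict) -> None:
    """Write a flat metrics dict as both JSON and a two-column CSV."""
    prefix = str(prefix)
    with open(f"{prefix}.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    with open(f"{prefix}.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metric", "value"])
        for k in sorted(metrics):
            w.writerow([k, metrics[k]])


def save_checkpoint(path, model, extra: dict | None = None) -> None:
    """Portable network checkpoint: parameter arrays + config in one archive."""
    state = model.get_state()
    meta = {"config": asdict(model.cfg)}
    meta.update(extra or {})
    np.savez(str(path), __meta__=json.dumps(meta, sort_keys=True), **state)


def load_checkpoint(path):
    """Load a checkpoint -> (rebuilt model, meta dict)."""
    from .network import NetworkConfig, build_network

    with np.load(str(path), allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = build_network(NetworkConfig(**meta["config"]))
    model.set_state(state)
    return model, meta


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(str(path), "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def log_stage(stage: str, seed, t_start: float, **info) -> None:
    """One structured log line per pipeline stage."""
    fields = {"stage": stage, "seed": seed,
              "duration_s": round(time.time() - t_start, 3), **info}
    logger.info(" ".join(f"{k}={v}" for k, v in fields.items()))
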