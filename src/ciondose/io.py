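"""Serialization: NIfTI volumes, per-beamlet dataset layout, manifests.

A dataset is one directory per beamlet holding ``ct.nii.gz``,
``dose.nii.gz``, ``alpha.nii.gz``, ``beta.nii.gz`` (NIfTI-1, float32, 1 mm
isotropic) plus ``meta.json`` with the beam parameters, seeds and label
scaling factors. A ``manifest.json`` at the dataset root lists the beamlet
directories with their train/val/test split.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grids import CTVolume, FieldVolume
from .preprocess import LABEL_SCALE

FORMAT_VERSION = 1


def write_volume(vol: CTVolume | FieldVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 float32 with its spacing in the affine."""
    arr = vol.hu if isinstance(vol, CTVolume) else vol.values
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing)
    quantity = "ct" if isinstance(vol, CTVolume) else vol.quantity
    img.header["descrip"] = f"ciondose:{quantity}".encode()
    nib.save(img, str(path))


def read_volume(path: str | Path, expect: str | None = None,
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)):
    """Read a NIfTI volume written by :func:`write_volume`.

    ``expect`` ("ct", "dose", "alpha" or "beta") is checked against the
    stored quantity tag; anisotropic or mismatched spacing is rejected.
    """
    img = nib.load(str(path))
    zooms = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    if zooms != tuple(spacing):
        raise ValueError(
            f"{path}: spacing {zooms} does not match expected {tuple(spacing)}")
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode()
    quantity = descrip.split(":", 1)[1] if descrip.startswith("ciondose:") else None
    if expect is not None and quantity is not None and quantity != expect:
        raise ValueError(f"{path}: stored quantity {quantity!r}, expected {expect!r}")
    data = np.asarray(img.dataobj, dtype=np.float32)
    if (expect or quantity) == "ct":
        return CTVolume(hu=data, spacing=spacing)
    return FieldVolume(values=data, quantity=expect or quantity, spacing=spacing)


def write_beamlet_dir(
    out_dir: str | Path,
    ct: CTVolume,
    dose: FieldVolume,
    alpha: FieldVolume,
    beta: FieldVolume,
    meta: dict,
) -> Path:
    """Write one beamlet's volumes + metadata; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(ct, out / "ct.nii.gz")
    write_volume(dose, out / "dose.nii.gz")
    write_volume(alpha, out / "alpha.nii.gz")
    write_volume(beta, out / "beta.nii.gz")
    meta = dict(meta)
    meta.setdefault("format_version", FORMAT_VERSION)
    meta.setdefault("label_scale", LABEL_SCALE)
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def read_beamlet_dir(path: str | Path):
    """Read one beamlet directory -> (ct, dose, alpha, beta, meta)."""
    p = Path(path)
    meta = json.loads((p / "meta.json").read_text())
    ct = read_volume(p / "ct.nii.gz", expect="ct")
    dose = read_volume(p / "dose.nii.gz", expect="dose")
    alpha = read_volume(p / "alpha.nii.gz", expect="alpha")
    beta = read_volume(p / "beta.nii.gz", expect="beta")
    return ct, dose, alpha, beta, meta


@dataclass
class DatasetManifest:
    """Per-beamlet metadata plus disjoint train/val/test splits."""

    entries: list[dict] = field(default_factory=list)
    format_version: int = FORMAT_VERSION
    config_hash: str = ""

    def __post_init__(self) -> None:
        names = [e["name"] for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate beamlet names in manifest")

    def split(self, which: str) -> list[dict]:
        return [e for e in self.entries if e["split"] == which]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"format_version": self.format_version,
             "config_hash": self.config_hash,
             "entries": self.entries}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        d = json.loads(Path(path).read_text())
        return cls(entries=d["entries"], format_version=d["format_version"],
                   config_hash=d.get("config_hash", ""))


def config_hash(obj: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def save_config(cfg_dict: dict, path: str | Path) -> None:
    """Write a fully materialized configuration as YAML (with its hash)."""
    payload = dict(cfg_dict)
    payload["config_hash"] = config_hash(cfg_dict)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_config(path: str | Path) -> dict:
    """Read a YAML configuration; verifies the embedded hash if present."""
    payload = yaml.safe_load(Path(path).read_text())
    stored = payload.pop("config_hash", None)
    if stored is not None and stored != config_hash(payload):
        raise ValueError(f"{path}: config hash mismatch (file edited?)")
    return payload


def save_samples(path: str | Path, **arrays) -> None:
    """Write packed training arrays with a format-version stamp."""
    np.savez_compressed(path, format_version=FORMAT_VERSION, **arrays)


def load_samples(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as z:
        if int(z["format_version"]) != FORMAT_VERSION:
            raise ValueError("unsupported sample-shard format version")
        return {k: z[k] for k in z.files if k != "format_version"}
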