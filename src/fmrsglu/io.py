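"""Dataset containers, result tables, and run manifests.

The native container for a subject dataset is a pair of files sharing a
stem: ``<stem>.json`` (acquisition parameters, design, ground truth, seed,
BOLD series) and ``<stem>.c16`` (little-endian complex128 binary blob
holding the per-TR FIDs followed by the water reference), a lossless
round-trip of the in-memory arrays.  A minimal NIfTI-MRS-style export is
provided for interoperability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .params import AcquisitionParams, BlockDesign, DataError, FidSeries
from .synthdata import GroundTruth, SubjectDataset

_REQUIRED = ("spectrometer_freq", "spectral_width", "n_points", "tr",
             "n_averages", "reference_ppm")


def _truth_to_dict(truth: GroundTruth) -> dict:
    d = dataclasses.asdict(truth)
    if d.get("eddy_params") is not None:
        d["eddy_params"] = list(d["eddy_params"])
    return d


def _truth_from_dict(d: dict) -> GroundTruth:
    d = dict(d)
    if d.get("eddy_params") is not None:
        d["eddy_params"] = tuple(d["eddy_params"])
    return GroundTruth(**d)


def write_dataset(ds: SubjectDataset, stem: str | Path) -> None:
    """Write a subject dataset as JSON header + complex binary blob."""
    stem = Path(stem)
    header = {
        "format": "fmrsglu-dataset",
        "version": __version__,
        "subject_id": ds.fids.subject_id,
        "params": dataclasses.asdict(ds.fids.params),
        "design": dataclasses.asdict(ds.design),
        "truth": _truth_to_dict(ds.truth),
        "seed": ds.seed,
        "csf_fraction": ds.csf_fraction,
        "condition_labels": [str(x) for x in ds.fids.condition_labels],
        "bold": [float(x) for x in ds.bold],
        "n_trs": int(len(ds.fids)),
        "n_points": int(ds.fids.fids.shape[1]),
        "dtype": "<c16",
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=1))
    blob = np.concatenate([ds.fids.fids.ravel(), ds.water_reference])
    blob.astype("<c16").tofile(stem.with_suffix(".c16"))


def read_dataset(stem: str | Path) -> SubjectDataset:
    """Read a dataset written by :func:`write_dataset`."""
    stem = Path(stem)
    try:
        header = json.loads(stem.with_suffix(".json").read_text())
    except FileNotFoundError as e:
        raise DataError(f"missing header file: {e.filename}") from e
    for key in ("params", "design", "truth", "seed", "csf_fraction",
                "condition_labels", "bold", "n_trs", "n_points"):
        if key not in header:
            raise DataError(f"dataset header missing field {key!r}")
    for key in _REQUIRED:
        if key not in header["params"]:
            raise DataError(f"dataset header missing field params.{key!r}")
    params = AcquisitionParams(**header["params"])
    design = BlockDesign(**header["design"])
    truth = _truth_from_dict(header["truth"])
    n_trs, n_points = header["n_trs"], header["n_points"]
    expected = n_trs * n_points + n_points
    blob = np.fromfile(stem.with_suffix(".c16"), dtype="<c16")
    if blob.size != expected:
        raise DataError(
            f"truncated binary blob: expected {expected * 16} bytes, got "
            f"{blob.size * 16} (short at byte offset {blob.size * 16})")
    fids = blob[: n_trs * n_points].reshape(n_trs, n_points)
    water = blob[n_trs * n_points:]
    series = FidSeries(fids=fids,
                       condition_labels=np.array(header["condition_labels"]),
                       params=params, subject_id=header["subject_id"])
    return SubjectDataset(fids=series, water_reference=water,
                          bold=np.array(header["bold"], dtype=float),
                          design=design, csf_fraction=header["csf_fraction"],
                          truth=truth, seed=header["seed"])


def manifest_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, seed: int) -> str:
    """Write the run manifest (config hash, seed, software version)."""
    h = manifest_hash(config)
    Path(path).write_text(json.dumps(
        {"manifest_hash": h, "seed": seed, "version": __version__,
         "config": config}, indent=1, default=str))
    return h


def write_table(df, path: str | Path, manifest: str = "") -> None:
    """TSV output; the first line carries the manifest hash as a comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# manifest: {manifest}\n")
        df.to_csv(fh, sep="\t", index=False)


def export_nifti_mrs(ds: SubjectDataset, path: str | Path) -> None:
    """Minimal NIfTI-MRS-style export: complex64 image of shape
    (1, 1, 1, n_points, n_trs) with a JSON header extension."""
    import nibabel as nib

    data = np.ascontiguousarray(ds.fids.fids.T[None, None, None, :, :],
                                dtype=np.complex64)
    img = nib.Nifti2Image(data, affine=np.eye(4))
    img.header["pixdim"][4] = ds.fids.params.dwell
    meta = {
        "SpectrometerFrequency": [ds.fids.params.spectrometer_freq],
        "ResonantNucleus": ["1H"],
        "SpectralWidth": ds.fids.params.spectral_width,
        "RepetitionTime": ds.fids.params.tr,
        "EchoTime": ds.fids.params.te,
    }
    ext = nib.nifti1.Nifti1Extension("comment", json.dumps(meta).encode())
    img.header.extensions.append(ext)
    nib.save(img, str(path))


def import_nifti_mrs(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read back a :func:`export_nifti_mrs` file -> (fids, metadata)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    fids = data[0, 0, 0].T
    meta = {}
    for ext in img.header.extensions:
        try:
            meta = json.loads(ext.get_content().decode())
            break
        except Exception:
            continue
    return fids, meta
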