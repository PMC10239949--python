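"""File formats: multi-page TIFF / DICOM clips, ROI JSON, tidy CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .gas import BloodGas
from .grading import LambTimeline
from .quant import LUSClip, ROI

__all__ = [
    "write_clip_tiff",
    "read_clip_tiff",
    "write_clip_dicom",
    "read_clip_dicom",
    "read_clip",
    "write_rois_json",
    "read_rois_json",
    "timelines_to_frame",
    "frame_to_timelines",
    "read_blood_gas_csv",
    "write_blood_gas_csv",
]


def _clip_meta(clip: LUSClip) -> dict:
    return {
        "frame_rate": clip.frame_rate,
        "acquisition_time_min": clip.acquisition_time_min,
        "lamb_id": clip.lamb_id,
        "side": clip.side,
        **clip.metadata,
    }


def write_clip_tiff(clip: LUSClip, path: str | Path) -> None:
    """Write a clip as 8-bit multi-page TIFF with JSON metadata."""
    tifffile.imwrite(
        str(path),
        clip.frames.astype(np.uint8),
        photometric="minisblack",
        description=json.dumps(_clip_meta(clip)),
    )


def read_clip_tiff(path: str | Path) -> LUSClip:
    with tifffile.TiffFile(str(path)) as tf:
        frames = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    return LUSClip(
        frames=np.atleast_3d(frames) if frames.ndim == 2 else frames,
        frame_rate=float(meta.pop("frame_rate", 15.0)),
        acquisition_time_min=float(meta.pop("acquisition_time_min", 0.0)),
        lamb_id=str(meta.pop("lamb_id", "")),
        side=str(meta.pop("side", "left")),
        metadata=meta,
    )


def write_clip_dicom(clip: LUSClip, path: str | Path) -> None:
    """Write a clip as an (uncompressed) multi-frame secondary-capture DICOM."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.PatientID = clip.lamb_id or "unknown"
    ds.SeriesDescription = f"{clip.side} lung, t={clip.acquisition_time_min} min"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = clip.n_frames
    ds.Rows, ds.Columns = clip.shape
    ds.CineRate = int(round(clip.frame_rate))
    ds.ImageComments = json.dumps(_clip_meta(clip))
    ds.PixelData = clip.frames.astype(np.uint8).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_clip_dicom(path: str | Path) -> LUSClip:
    import pydicom

    ds = pydicom.dcmread(str(path))
    frames = ds.pixel_array
    if frames.ndim == 2:
        frames = frames[None]
    try:
        meta = json.loads(getattr(ds, "ImageComments", "") or "{}")
    except json.JSONDecodeError:
        meta = {}
    return LUSClip(
        frames=frames,
        frame_rate=float(meta.pop("frame_rate", getattr(ds, "CineRate", 15.0))),
        acquisition_time_min=float(meta.pop("acquisition_time_min", 0.0)),
        lamb_id=str(meta.pop("lamb_id", getattr(ds, "PatientID", ""))),
        side=str(meta.pop("side", "left")),
        metadata=meta,
    )


def read_clip(path: str | Path) -> LUSClip:
    """Read a clip, dispatching on the file extension (.tif/.tiff vs .dcm)."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        return read_clip_tiff(p)
    return read_clip_dicom(p)


def write_rois_json(rois_by_clip: dict[str, list[ROI]], path: str | Path) -> None:
    payload = {k: [r.to_dict() for r in v] for k, v in rois_by_clip.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois_json(path: str | Path) -> dict[str, list[ROI]]:
    payload = json.loads(Path(path).read_text())
    return {k: [ROI.from_dict(d) for d in v] for k, v in payload.items()}


def timelines_to_frame(timelines: list[LambTimeline]) -> pd.DataFrame:
    """Tidy long table: one row per (lamb, timepoint, side)."""
    rows = []
    for tl in timelines:
        sides = sorted(set(tl.grades) | set(tl.epa))
        for i, t in enumerate(tl.timepoints_min):
            for side in sides:
                rows.append(
                    {
                        "lamb_id": tl.lamb_id,
                        "group": tl.group,
                        "time_min": float(t),
                        "side": side,
                        "grade": float(tl.grades[side][i]) if side in tl.grades else np.nan,
                        "epa": float(tl.epa[side][i]) if side in tl.epa else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def frame_to_timelines(df: pd.DataFrame) -> list[LambTimeline]:
    out = []
    for lamb_id, sub in df.groupby("lamb_id", sort=True):
        times = np.array(sorted(sub["time_min"].unique()))
        grades: dict[str, np.ndarray] = {}
        epa: dict[str, np.ndarray] = {}
        for side, ss in sub.groupby("side"):
            g = np.full(times.size, np.nan)
            e = np.full(times.size, np.nan)
            idx = np.searchsorted(times, ss["time_min"].to_numpy())
            g[idx] = ss["grade"].to_numpy()
            e[idx] = ss["epa"].to_numpy()
            if np.isfinite(g).any():
                grades[side] = g
            if np.isfinite(e).any():
                epa[side] = e
        out.append(
            LambTimeline(
                lamb_id=str(lamb_id),
                group=str(sub["group"].iloc[0]),
                timepoints_min=times,
                grades=grades,
                epa=epa,
            )
        )
    return out


def write_blood_gas_csv(records: list[BloodGas], path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_min": [r.time_min for r in records],
            "fio2": [r.fio2 for r in records],
            "pao2_mmhg": [r.pao2_mmhg for r in records],
            "paco2_mmhg": [r.paco2_mmhg for r in records],
            "sao2_pct": [r.sao2_pct for r in records],
            "temp_c": [r.temperature_c for r in records],
        }
    ).to_csv(path, index=False, float_format="%.6g")


def read_blood_gas_csv(path: str | Path) -> list[BloodGas]:
    df = pd.read_csv(path)
    return [
        BloodGas(
            time_min=float(r.time_min),
            fio2=float(r.fio2),
            pao2_mmhg=float(r.pao2_mmhg),
            paco2_mmhg=float(r.paco2_mmhg),
            temperature_c=float(r.temp_c),
            sao2_pct=None if pd.isna(r.sao2_pct) else float(r.sao2_pct),
        )
        for r in df.itertuples()
    ]
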