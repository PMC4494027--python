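"""NIfTI-1 and tab-separated readers/writers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from blockmvpa.design import EVENT_COLUMNS, EventTable, SUBJECTIVE_LABELS
from blockmvpa.errors import EventTableError, VolumeIOError
from blockmvpa.glm import ZMap
from blockmvpa.simulate import BoldRun


def write_bold(run: BoldRun, path) -> None:
    """Write a run to NIfTI-1, preserving TR and voxel geometry."""
    img = nib.Nifti1Image(run.data, run.affine)
    img.header.set_zooms((*run.voxel_size_mm, run.tr_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_bold(path) -> BoldRun:
    """Read a 4-D NIfTI-1 run; losslessly inverts :func:`write_bold`."""
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise VolumeIOError(f"{path}: expected 4-D data, got shape {data.shape}")
    zooms = img.header.get_zooms()
    return BoldRun(
        data=data,
        tr_s=float(zooms[3]),
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        affine=np.asarray(img.affine, dtype=float),
    )


def write_zmap(zmap: ZMap, path) -> None:
    affine = zmap.affine if zmap.affine is not None else np.eye(4)
    img = nib.Nifti1Image(zmap.data, affine)
    img.header["descrip"] = zmap.contrast_name.encode()[:79]
    nib.save(img, str(path))


def read_zmap(path) -> ZMap:
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected 3-D z-map, got shape {data.shape}")
    name = img.header["descrip"].tobytes().rstrip(b"\x00").decode() or "contrast"
    return ZMap(data, contrast_name=name, affine=np.asarray(img.affine, float))


def write_mask(mask: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(
        np.asarray(mask, dtype=np.uint8), np.eye(4) if affine is None else affine
    )
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    img = _load(path)
    return np.asarray(img.dataobj) > 0


def _load(path):
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        img.header  # force header parse
        np.asarray(img.dataobj)  # force data read so truncation surfaces here
    except VolumeIOError:
        raise
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeIOError(f"{path}: cannot read volume ({exc})") from exc
    return img


def write_events(events: EventTable, path) -> None:
    """Events as a tab-separated table (BIDS-events dialect)."""
    events.frame.to_csv(path, sep="\t", index=False)


def read_events(path, n_volumes: int | None = None, tr_s: float | None = None) -> EventTable:
    """Read a tab-separated events file; unknown columns are preserved.

    With ``n_volumes`` and ``tr_s`` given, onsets beyond the run are
    rejected on load.
    """
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise EventTableError(f"{path}: missing required column(s) {missing}")
    bad = set(frame["subjective"].astype(str)) - set(SUBJECTIVE_LABELS)
    if bad:
        raise EventTableError(f"{path}: invalid subjective value(s) {sorted(bad)}")
    if n_volumes is not None and tr_s is not None:
        run_end = n_volumes * tr_s
        if (frame["onset"] >= run_end).any():
            raise EventTableError(
                f"{path}: onset beyond the {run_end} s run end"
            )
    return EventTable(frame)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
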