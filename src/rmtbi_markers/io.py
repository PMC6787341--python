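"""File-format plumbing: TSV spot tables, TCK tractograms, NIfTI volumes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import nibabel as nib
from nibabel.streamlines import Tractogram, save as nib_save_trk, load as nib_load_trk

from rmtbi_markers.rppm import SPOT_COLUMNS, DataError


def read_spot_table(path) -> pd.DataFrame:
    """Read a tab-separated spot table with the canonical columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return df


def write_spot_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tck(path) -> list[np.ndarray]:
    """Load streamlines from a TCK file, in world (RAS mm) coordinates."""
    tf = nib_load_trk(str(path))
    return [np.asarray(s, float) for s in tf.streamlines]


def write_tck(streamlines: list[np.ndarray], path) -> None:
    tg = Tractogram([np.asarray(s, np.float32) for s in streamlines],
                    affine_to_rasmm=np.eye(4))
    nib_save_trk(tg, str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), affine), str(path))
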