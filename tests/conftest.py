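from __future__ import annotations

import numpy as np
import pytest

from lungseg.phantom import PhantomSpec, generate


def make_dicom(path, pixels_u16: np.ndarray, slope=1, intercept=-1024,
               spacing=(0.692, 0.692), n_frames=1):
    """Write a minimal single-frame CT DICOM with the given stored values."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = pixels_u16.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.PixelSpacing = [spacing[0], spacing[1]]
    if n_frames > 1:
        ds.NumberOfFrames = n_frames
    ds.PixelData = np.ascontiguousarray(pixels_u16, dtype="<u2").tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path


@pytest.fixture(scope="session")
def phantom_small():
    """A scaled-down clean thorax phantom (fast enough for per-stage tests)."""
    spec = PhantomSpec.scaled(192, seed=7)
    ct, truth, struct = generate(spec)
    return spec, ct, truth, struct


@pytest.fixture(scope="session")
def phantom_noisy_small():
    spec = PhantomSpec.scaled(192, seed=7, noise_sd=20.0)
    ct, truth, struct = generate(spec)
    return spec, ct, truth, struct
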