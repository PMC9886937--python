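import numpy as np
import pytest

from pelvidet import CTVolume, LabelVolume, PhantomSpec, gen_phantom


@pytest.fixture(scope="session")
def phantom12():
    """The reference phantom: 12 nodes, 8 vessels, seed 1."""
    return gen_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def phantom_large():
    """A larger phantom with >= 5000 node voxels for distributional checks."""
    return gen_phantom(
        PhantomSpec(shape=(26, 224, 224), n_nodes=30, node_radius_px=(4, 7),
                    node_radius_z=(1, 2), n_vessels=8, seed=11)
    )


def make_volume(voxels, spacing=(3.0, 0.648, 0.648)):
    return CTVolume(voxels=np.asarray(voxels, dtype=float), spacing=spacing)


def make_mask(mask, role, vol):
    return LabelVolume(mask=np.asarray(mask).astype(np.uint8), role=role, frame=vol)


def write_dicom_slice(path, pixels, z_mm, slope=1.0, intercept=-1024.0):
    """Write one synthetic CT DICOM slice (uint16 stored pixels)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = pixels.shape
    ds.ImagePositionPatient = [0.0, 0.0, float(z_mm)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [0.648, 0.648]
    ds.SliceThickness = 2.5
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.PixelData = np.asarray(pixels, dtype="<u2").tobytes()
    ds.save_as(str(path), enforce_file_format=True)
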