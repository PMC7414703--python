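"""Raster/mask/manifest I/O and physical-coordinate bookkeeping."""

import json

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from PIL import Image

from octanpa import (
    BinaryMask,
    ContractError,
    EnFaceImage,
    FormatError,
    ManifestError,
    MetadataError,
    load_manifest,
    read_enface,
    read_mask,
    write_mask,
)


class TestReadEnface:
    def test_widefield_tiff_with_sidecar_recovers_field(self, tmp_path):
        """600 × 1000 px at 0.015 mm/px is the 9 × 15 mm widefield scan."""
        arr = np.arange(600 * 1000, dtype=np.uint16).reshape(600, 1000) % 4096
        tifffile.imwrite(tmp_path / "scan.tif", arr)
        (tmp_path / "scan.json").write_text(
            json.dumps({"pixel_size_mm": 0.015, "field_mm": [9.0, 15.0], "plexus": "SCP"})
        )
        img = read_enface(tmp_path / "scan.tif")
        assert img.pixel_size_mm == 0.015
        assert img.field_mm == (9.0, 15.0)
        assert img.plexus == "SCP"
        assert img.pixels.dtype == np.float64
        # intensities untouched in scale
        np.testing.assert_array_equal(img.pixels, arr.astype(np.float64))
        assert img.scan_area_mm2 == pytest.approx(9.0 * 15.0)

    def test_tiny_png_identity_read(self, tmp_path):
        Image.fromarray(np.zeros((2, 2), dtype=np.uint8)).save(tmp_path / "z.png")
        img = read_enface(tmp_path / "z.png", pixel_size_mm=1.0)
        np.testing.assert_array_equal(img.pixels, np.zeros((2, 2)))

    def test_rgb_png_rejected(self, tmp_path):
        Image.fromarray(np.zeros((4, 4, 3), dtype=np.uint8)).save(tmp_path / "rgb.png")
        with pytest.raises(FormatError):
            read_enface(tmp_path / "rgb.png", pixel_size_mm=1.0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_enface(tmp_path / "nope.tif", pixel_size_mm=1.0)

    def test_missing_pixel_size(self, tmp_path):
        Image.fromarray(np.zeros((4, 4), dtype=np.uint8)).save(tmp_path / "a.png")
        with pytest.raises(MetadataError):
            read_enface(tmp_path / "a.png")

    def test_nonpositive_pixel_size(self, tmp_path):
        Image.fromarray(np.zeros((4, 4), dtype=np.uint8)).save(tmp_path / "a.png")
        with pytest.raises(MetadataError):
            read_enface(tmp_path / "a.png", pixel_size_mm=0.0)

    def test_inconsistent_field_rejected(self):
        """Shape × pixel size must agree with field_mm within one pixel."""
        with pytest.raises(MetadataError):
            EnFaceImage(np.zeros((100, 100)), pixel_size_mm=0.015, field_mm=(9.0, 15.0))


class TestMaskRoundTrip:
    @settings(max_examples=30, deadline=None)
    @given(
        arrays(
            np.uint8,
            st.tuples(st.integers(2, 24), st.integers(2, 24)),
            elements=st.integers(0, 1),
        )
    )
    def test_roundtrip_bit_exact(self, arr):
        """write_mask ∘ read_mask is the identity for every binary raster."""
        import tempfile
        from pathlib import Path

        mask = BinaryMask(pixels=arr, pixel_size_mm=0.015, role="vessel")
        with tempfile.TemporaryDirectory() as d:
            p = Path(d) / "m.png"
            write_mask(mask, p)
            back = read_mask(p, 0.015)
        np.testing.assert_array_equal(back.pixels, mask.pixels)

    def test_all_zero_mask(self, tmp_path):
        mask = BinaryMask(np.zeros((5, 5), np.uint8), 0.015)
        write_mask(mask, tmp_path / "z.png")
        assert read_mask(tmp_path / "z.png", 0.015).pixel_count == 0

    def test_nonbinary_value_rejected(self, tmp_path):
        Image.fromarray(np.full((4, 4), 128, dtype=np.uint8)).save(tmp_path / "g.png")
        with pytest.raises(FormatError):
            read_mask(tmp_path / "g.png", 0.015)

    def test_nonbinary_array_rejected(self):
        with pytest.raises(ContractError):
            BinaryMask(np.full((3, 3), 2, dtype=np.uint8), 0.015)


class TestManifest:
    HEADER = "patient_id,eye,plexus,timepoint,image_path\n"

    def _write_image(self, tmp_path, name="im.png"):
        Image.fromarray(np.zeros((4, 4), dtype=np.uint8)).save(tmp_path / name)
        return name

    def test_single_valid_row(self, tmp_path):
        name = self._write_image(tmp_path)
        (tmp_path / "m.csv").write_text(self.HEADER + f"P01,OD,SCP,T0,{name}\n")
        manifest = load_manifest(tmp_path / "m.csv")
        assert len(manifest) == 1
        rec = manifest.records[0]
        assert rec.key == ("P01", "OD", "SCP", "T0")
        assert rec.image_path.exists()

    def test_duplicate_key_rejected(self, tmp_path):
        name = self._write_image(tmp_path)
        rows = f"P01,OD,SCP,T0,{name}\n" * 2
        (tmp_path / "m.csv").write_text(self.HEADER + rows)
        with pytest.raises(ManifestError, match="duplicate"):
            load_manifest(tmp_path / "m.csv")

    @pytest.mark.parametrize(
        "row,match",
        [
            ("P01,OD,SCP,T5,{img}", "timepoint"),
            ("P01,XX,SCP,T0,{img}", "eye"),
            ("P01,OD,XCP,T0,{img}", "plexus"),
            ("P01,OD,SCP,T0,missing.png", "not resolvable"),
        ],
    )
    def test_invalid_rows_rejected(self, tmp_path, row, match):
        img = self._write_image(tmp_path)
        (tmp_path / "m.csv").write_text(self.HEADER + row.format(img=img) + "\n")
        with pytest.raises(ManifestError, match=match):
            load_manifest(tmp_path / "m.csv")

    def test_missing_column_rejected(self, tmp_path):
        (tmp_path / "m.csv").write_text("patient_id,eye\nP01,OD\n")
        with pytest.raises(ManifestError, match="missing required columns"):
            load_manifest(tmp_path / "m.csv")
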