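"""Standard-format I/O: multi-page TIFF cone-catch images, PNG masks, CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .vision import ConeCatchImage


def write_image(img: ConeCatchImage, directory, stem=None):
    """Write catches as a 4-page float32 TIFF and the mask as an 8-bit PNG."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or img.id or "image"
    pages = np.moveaxis(img.catches.astype(np.float32), 2, 0)
    tifffile.imwrite(directory / f"{stem}.tif", pages,
                     photometric="minisblack")
    Image.fromarray((img.mask * 255).astype(np.uint8)).save(directory / f"{stem}_mask.png")
    return directory / f"{stem}.tif"


def read_image(tif_path, px_per_mm, image_id=None) -> ConeCatchImage:
    tif_path = Path(tif_path)
    pages = tifffile.imread(tif_path)
    if pages.ndim != 3 or pages.shape[0] != 4:
        raise ValueError(f"{tif_path} is not a 4-page cone-catch TIFF")
    catches = np.moveaxis(pages.astype(float), 0, 2)
    mask_path = tif_path.with_name(tif_path.stem + "_mask.png")
    mask = np.asarray(Image.open(mask_path)) > 127
    return ConeCatchImage(catches, mask, px_per_mm,
                          id=image_id or tif_path.stem)


def write_metric_table(vectors, species_map, path):
    """One row per individual x distance: id, species, distance_mm, valid, 157 metrics."""
    rows = []
    for v in vectors:
        row = {"id": v.individual_id,
               "species": species_map.get(v.individual_id, ""),
               "distance_mm": v.distance_mm, "valid": v.valid}
        row.update(v.values)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
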