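"""Blinded-analysis workflow.

Duplicates a folder of images under random numeric codes so the analyst
cannot tell experimental groups apart, saves a key table, and re-attaches
the original names to result tables once measurement is done.  Originals
are never modified or deleted.
"""

from __future__ import annotations

import shutil
import warnings
from dataclasses import dataclass
from pathlib import Path
from random import Random

import pandas as pd

from .core import ResultTable, TailquantError

__all__ = ["BlindingKey", "BlindingError", "blind_folder", "unblind_table"]

IMAGE_EXTENSIONS = {".tif", ".tiff", ".png"}
_MAX_DRAWS = 1000


class BlindingError(TailquantError):
    pass


@dataclass
class BlindingKey:
    """Bijective original-name ↔ code-name table.

    Codes are zero-padded 6-digit random integers with the original file
    extension preserved, so coded files stay openable but carry no
    information about their origin.
    """

    mapping: dict[str, str]  # original_name -> code_name

    def __post_init__(self) -> None:
        codes = list(self.mapping.values())
        if len(set(codes)) != len(codes):
            raise BlindingError("key is not bijective: duplicate code names")

    @property
    def inverse(self) -> dict[str, str]:
        return {code: orig for orig, code in self.mapping.items()}

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [{"original_name": o, "code_name": c} for o, c in sorted(self.mapping.items())]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BlindingKey":
        df = pd.read_csv(path)
        missing = {"original_name", "code_name"} - set(df.columns)
        if missing:
            raise BlindingError(f"{path}: key CSV missing columns {sorted(missing)}")
        return cls(dict(zip(df["original_name"].astype(str), df["code_name"].astype(str))))


def blind_folder(
    in_dir: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    key_path: str | Path | None = None,
) -> BlindingKey:
    """Duplicate every image in ``in_dir`` into ``out_dir`` under a random code.

    With a seed the code assignment is reproducible; without, codes are
    entropy-seeded for true blinding.  Non-image files are skipped with a
    warning.  The key is returned and, if ``key_path`` is given, written
    as CSV.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    if in_dir.resolve() == out_dir.resolve():
        raise BlindingError("output folder must differ from the input folder")
    files = sorted(p for p in in_dir.iterdir() if p.is_file())
    images = [p for p in files if p.suffix.lower() in IMAGE_EXTENSIONS]
    for p in files:
        if p.suffix.lower() not in IMAGE_EXTENSIONS:
            warnings.warn(f"skipping non-image file {p.name}", stacklevel=2)
    if not images:
        raise BlindingError(f"no image files found in {in_dir}")

    rng = Random(seed)
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for p in images:
        for draw in range(_MAX_DRAWS + 1):
            if draw == _MAX_DRAWS:
                raise BlindingError(f"no collision-free code after {_MAX_DRAWS} draws")
            code = f"{rng.randrange(1_000_000):06d}{p.suffix.lower()}"
            if code not in used:
                break
        used.add(code)
        mapping[p.name] = code

    out_dir.mkdir(parents=True, exist_ok=True)
    for orig, code in mapping.items():
        shutil.copy2(in_dir / orig, out_dir / code)
    key = BlindingKey(mapping)
    if key_path is not None:
        key.to_csv(key_path)
    return key


def unblind_table(results: ResultTable, key: BlindingKey) -> ResultTable:
    """Map coded image ids in a result table back to their original names.

    Values are untouched; only the identifiers are remapped.  Ids may be
    code filenames or their stems.  Unknown codes raise an error listing
    every offender.
    """
    inv = key.inverse
    stem_inv = {Path(code).stem: orig for code, orig in inv.items()}

    def remap(image_id: str) -> str | None:
        return inv.get(image_id) or stem_inv.get(image_id)

    unknown = sorted({i for i in results.df["image_id"] if remap(str(i)) is None})
    if unknown:
        raise BlindingError(f"codes not present in the key: {unknown}")
    df = results.df.copy()
    df["image_id"] = [remap(str(i)) for i in df["image_id"]]
    return ResultTable(df)
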