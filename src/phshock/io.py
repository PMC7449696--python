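"""Reading and writing pipeline tables.

Event tables travel as plain CSV with a JSON sidecar manifest
(``<name>.manifest.json``) holding sample metadata — timepoint, condition,
buffer pH, excluded-event counts.  Expression matrices are genes x samples
TSV.  A channel-name mapping lets CSV exports from different instrument
filter sets be ingested under the package's canonical channel names.

Manifests are written with sorted keys and no timestamps, so re-running a
pipeline with the same inputs reproduces files byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

CANONICAL_CHANNELS = (
    "fsc_area", "fsc_width", "ssc", "ch405", "ch488", "ch_red", "ch_bv421",
)


def _manifest_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".manifest.json")


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_csv(path, index=False)
    meta = {k: v for k, v in events.attrs.items()}
    _manifest_path(path).write_text(json.dumps(meta, sort_keys=True, indent=1, default=str))
    return path


def read_events(path, channel_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an event CSV, renaming instrument channel names to canonical ones.

    ``channel_map`` maps file column names to canonical names, e.g.
    ``{"405:525/50": "ch405"}``.
    """
    path = Path(path)
    events = pd.read_csv(path)
    if channel_map:
        events = events.rename(columns=channel_map)
    manifest = _manifest_path(path)
    if manifest.exists():
        events.attrs = json.loads(manifest.read_text())
    return events


def write_tpm(tpm: pd.DataFrame, samples: pd.DataFrame, prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tpm_path = prefix.with_suffix(".tpm.tsv")
    sheet_path = prefix.with_suffix(".samples.tsv")
    tpm.to_csv(tpm_path, sep="\t")
    samples.to_csv(sheet_path, sep="\t", index=False)
    return tpm_path, sheet_path


def read_tpm(tpm_path, samples_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    return tpm, samples


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
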