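"""CSV report reading/writing with a provenance header block.

Every report carries commented header lines recording the configuration
hash and the seeds in effect, so a rerun can be verified byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_report(df: pd.DataFrame, path: str | Path, meta: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# {k}: {v}" for k, v in meta.items()]
    body = df.to_csv(index=False, float_format="%.6g", lineterminator="\n")
    path.write_text("\n".join(lines) + "\n" + body)
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_report_meta(path: str | Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = val.strip()
    return meta
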