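"""CSV and YAML I/O with seed provenance.

Every CSV written by the pipeline starts with a ``# seed=<int>`` comment
line so a run can be reproduced from its outputs alone; the readers skip
comment lines.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = ["write_table", "read_table", "save_config", "load_config"]


def write_table(df: pd.DataFrame, path, seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def save_config(config_dict: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
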