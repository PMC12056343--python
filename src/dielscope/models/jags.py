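"""Thin subprocess bridge to JAGS (via rjags/Rscript) for the binomial models.

The Gibbs/slice sampling engine is JAGS; the model code, data layout,
priors and seeds are produced here, and the stacked CODA draws are parsed
back into (chain, draw) arrays.  Chain RNG seeds are derived from the model
seed so runs are fully reproducible.
"""

from __future__ import annotations

import json
import re
import shutil
import subprocess
import tempfile
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["run_jags", "JagsError"]

_VEC = re.compile(r"^(.*)\[(\d+)(?:,(\d+))?\]$")


class JagsError(RuntimeError):
    """JAGS (via Rscript) failed; stderr is included in the message."""


def _to_jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


def run_jags(
    model_code: str,
    data: dict,
    params: list[str],
    *,
    n_chains: int = 3,
    n_adapt: int = 1000,
    n_burn: int = 1000,
    n_iter: int = 3000,
    thin: int = 2,
    seed: int = 0,
    inits: dict | None = None,
) -> dict[str, np.ndarray]:
    """Run a JAGS model and return draws.

    Returns a dict mapping each monitored parameter to an array of shape
    (n_chains, kept_draws) for scalars, (n_chains, kept_draws, k) for
    vectors and (n_chains, kept_draws, k, l) for matrices.
    """
    if shutil.which("Rscript") is None:
        raise JagsError("Rscript not found on PATH; JAGS models are unavailable")

    chain_inits = []
    for c in range(n_chains):
        ci = {k: _to_jsonable(v) for k, v in (inits or {}).items()}
        ci[".RNG.seed"] = int((seed & 0x7FFFFFFF) + 1000 * (c + 1) + 1)
        chain_inits.append(ci)

    with tempfile.TemporaryDirectory(prefix="dielscope_jags_") as tmp:
        tmp = Path(tmp)
        (tmp / "model.txt").write_text(model_code)
        (tmp / "data.json").write_text(
            json.dumps({k: _to_jsonable(v) for k, v in data.items()})
        )
        (tmp / "inits.json").write_text(json.dumps(chain_inits))
        (tmp / "params.txt").write_text("\n".join(params))
        out_csv = tmp / "draws.csv"
        driver = resources.files("dielscope.models") / "jags_driver.R"
        with resources.as_file(driver) as driver_path:
            proc = subprocess.run(
                [
                    "Rscript", str(driver_path), str(tmp / "model.txt"),
                    str(tmp / "data.json"), str(tmp / "inits.json"),
                    str(tmp / "params.txt"), str(n_adapt), str(n_burn),
                    str(n_iter), str(thin), str(out_csv),
                ],
                capture_output=True,
                text=True,
            )
        if proc.returncode != 0 or not out_csv.exists():
            raise JagsError(
                f"JAGS run failed (exit {proc.returncode}):\n{proc.stderr[-4000:]}"
            )
        raw = pd.read_csv(out_csv)

    chains = sorted(raw["chain"].unique())
    per_chain = [raw[raw.chain == c].drop(columns="chain").reset_index(drop=True) for c in chains]
    n_draws = min(len(pc) for pc in per_chain)

    out: dict[str, np.ndarray] = {}
    cols = per_chain[0].columns
    groups: dict[str, list[tuple[tuple[int, ...], str]]] = {}
    for col in cols:
        m = _VEC.match(col)
        if m:
            name = m.group(1)
            idx = (int(m.group(2)),) + ((int(m.group(3)),) if m.group(3) else ())
            groups.setdefault(name, []).append((idx, col))
        else:
            groups.setdefault(col, []).append(((), col))

    for name, members in groups.items():
        members.sort(key=lambda t: t[0])
        if members[0][0] == ():
            out[name] = np.stack([pc[name].to_numpy()[:n_draws] for pc in per_chain])
        else:
            dims = tuple(max(idx[d] for idx, _ in members) for d in range(len(members[0][0])))
            arr = np.empty((len(per_chain), n_draws, *dims))
            for idx, col in members:
                sl = tuple(i - 1 for i in idx)
                for c, pc in enumerate(per_chain):
                    arr[(c, slice(None), *sl)] = pc[col].to_numpy()[:n_draws]
            out[name] = arr
    return out
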