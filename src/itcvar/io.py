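"""CSV input/output and the seeded synthetic fixture generator.

All interchange files are plain UTF-8 CSV (comma separator, dot decimal,
mandatory header).  Output files carry ``#``-prefixed comment lines with
the configuration hash and seed so any result can be regenerated exactly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import simulate_isotherm
from .exceptions import DataError
from .estimation import ProtocolDesign, simulate_protocol
from .measurement import AdditionalErrors, ErrorParams, realize_titration
from .variance import standard_comparison

__all__ = ["read_heats", "write_table", "generate_fixtures"]

HEAT_COLUMNS = ("injection_index", "V_uL", "Q_uJ")


def write_table(df: pd.DataFrame, path, header_lines=()) -> None:
    """Write a CSV with leading ``#`` comment lines."""
    buf = _io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_heats(path, drop_first: bool = True) -> pd.DataFrame:
    """Read and validate a per-injection heat table.

    Expects columns ``injection_index`` (1-based), ``V_uL``, ``Q_uJ`` and
    optionally ``titration_id`` (defaults to 1).  Returns the table with an
    added boolean ``effective`` column (False for injection 1 when
    ``drop_first``).  Raises :class:`DataError` with the offending row
    number on malformed input.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except (OSError, pd.errors.ParserError) as e:
        raise DataError(f"cannot read {path}: {e}") from e
    missing = [c for c in HEAT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    if "titration_id" not in df.columns:
        df["titration_id"] = "1"

    out = pd.DataFrame()
    for col in ("injection_index", "titration_id", "V_uL", "Q_uJ"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int((vals.isna()).idxmax()) + 2  # +1 header, +1 1-based
            raise DataError(f"{path}: non-numeric or empty {col!r} at row {row}")
        out[col] = vals
    out["injection_index"] = out["injection_index"].astype(int)
    out["titration_id"] = out["titration_id"].astype(int)

    dup = out.duplicated(subset=["titration_id", "injection_index"])
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise DataError(f"{path}: duplicate (titration_id, injection_index) at row {row}")
    if (out["injection_index"] < 1).any():
        raise DataError(f"{path}: injection_index must be 1-based")
    if (out["V_uL"] <= 0).any():
        raise DataError(f"{path}: injection volumes must be > 0")

    out["effective"] = ~(drop_first & (out["injection_index"] == 1))
    if not out["effective"].any():
        raise DataError(
            f"{path}: no effective injections remain after dropping injection 1"
        )
    return out


def generate_fixtures(seed: int, outdir) -> list[Path]:
    """Write the standard synthetic test battery (byte-reproducible per seed).

    (a) noise-free isotherms at c = 10 and c = 1000;
    (b) a 5-replicate noisy set at c = 100 with basic errors;
    (c) the 4-group saturated/blank protocol at the NanoITC truth values
        with 1% additional errors (stand-in for experimental CaCl2/EDTA
        saturated and water-blank titrations).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    errs = ErrorParams()
    paths = []

    for c in (10, 1000):
        config, rxn = standard_comparison(c)
        iso = simulate_isotherm(config, rxn)
        p = outdir / f"isotherm_c{c}.csv"
        write_table(
            iso.to_frame(),
            p,
            [
                f"noise-free isotherm, c={c}, C_cell=1 mM, dH=-40 kJ/mol",
                "mole_ratio = cumulative injected titrant moles / initial titrand moles",
                f"seed: {seed}",
            ],
        )
        paths.append(p)

    config, rxn = standard_comparison(100)
    frames = []
    for rep in range(5):
        real = realize_titration(config, rxn, errs, rng=rng, replicate_id=rep + 1)
        frames.append(real.to_frame())
    p = outdir / "noisy_replicates_c100.csv"
    write_table(
        pd.concat(frames, ignore_index=True),
        p,
        ["5 noisy replicates, c=100, basic errors only", f"seed: {seed}"],
    )
    paths.append(p)

    data = simulate_protocol(
        truth=errs,
        add=AdditionalErrors(0.01, 0.01, 0.01),
        design=ProtocolDesign(),
        rng=rng,
    )
    for g in data.groups:
        tag = "blank" if g.is_blank else "saturated"
        p = outdir / f"{tag}_{g.V0:g}uL.csv"
        write_table(
            g.to_frame(),
            p,
            [
                f"synthetic {tag} titration group, V0={g.V0:g} uL "
                "(emulates CaCl2/EDTA saturated or water blank titrations)",
                f"seed: {seed}",
            ],
        )
        paths.append(p)
    return paths
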