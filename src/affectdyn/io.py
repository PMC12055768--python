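"""CSV readers and writers for session streams and derived outputs.

Session files mimic the export of observational-coding software: one
row per coded second with columns ``time_s,actor,code``, where each
actor's seconds must form a contiguous, duplicate-free 0..T-1 run.
Writers round-trip losslessly; absent model terms are written as
``N/A`` to match the reported parameter-table convention.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .codes import ACTORS, META_OF, CodeStream
from .descriptives import SessionSummary
from .model import DyadModel, InfluenceFunction, ModelParameters, RepairTerm

SESSION_COLUMNS = ["time_s", "actor", "code"]
PARAM_COLUMNS = ["actor", "a2", "r2", "UnSS", "nth", "pth", "kr", "sr"]


def read_session(path) -> tuple[CodeStream, CodeStream]:
    """Read a per-second session CSV into (therapist, client) streams."""
    df = pd.read_csv(path, dtype={"time_s": "Int64", "actor": str, "code": str})
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df[SESSION_COLUMNS].isna().any().any():
        bad = int(df[df[SESSION_COLUMNS].isna().any(axis=1)].index[0]) + 2
        raise ValueError(f"{path}: malformed row at line {bad}")
    streams: dict[str, CodeStream] = {}
    for actor in ACTORS:
        sub = df[df["actor"] == actor].sort_values("time_s")
        if sub.empty:
            raise ValueError(f"{path}: no rows for actor {actor!r}")
        times = sub["time_s"].to_numpy(dtype=int)
        dup = pd.Series(times).duplicated()
        if dup.any():
            raise ValueError(
                f"{path}: duplicated second {times[dup.to_numpy()][0]} for {actor}"
            )
        expected = np.arange(len(times))
        if not np.array_equal(times, expected):
            gap = int(expected[times != expected][0])
            raise ValueError(
                f"{path}: {actor} seconds are not contiguous from 0 "
                f"(first problem at second {gap})"
            )
        for line, code in zip(sub.index, sub["code"]):
            if code not in META_OF:
                raise ValueError(
                    f"{path}: unknown code {code!r} at line {int(line) + 2}"
                )
        streams[actor] = CodeStream(actor=actor, codes=tuple(sub["code"]))
    return streams["therapist"], streams["client"]


def write_session(therapist: CodeStream, client: CodeStream, path) -> None:
    rows = []
    for stream in (therapist, client):
        rows += [
            {"time_s": t, "actor": stream.actor, "code": code}
            for t, code in enumerate(stream.codes)
        ]
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


def write_summary(summaries: Iterable[SessionSummary], path) -> None:
    """One row per (session, actor, code) and per meta state."""
    rows = []
    for s in summaries:
        pct = s.per_code_percent
        for code, sec in s.per_code_seconds.items():
            rows.append(
                {"session": s.session_id, "actor": s.actor, "kind": "code",
                 "name": code, "seconds": sec, "percent": pct[code]}
            )
        mpct = s.meta_percent
        for meta, sec in s.meta_seconds.items():
            rows.append(
                {"session": s.session_id, "actor": s.actor, "kind": "meta",
                 "name": meta, "seconds": sec, "percent": mpct[meta]}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _fmt(value: float | None) -> str:
    return "N/A" if value is None else repr(float(value))


def write_params(model: DyadModel, path) -> None:
    """Parameter CSV with the reported column layout (N/A for absent terms)."""
    rows = []
    for p in (model.therapist, model.client):
        infl, rep = p.influence_from_partner, p.repair
        rows.append(
            {
                "actor": p.actor,
                "a2": _fmt(p.initial_state),
                "r2": _fmt(p.inertia),
                "UnSS": _fmt(p.unss),
                "nth": _fmt(infl.neg_threshold),
                "pth": _fmt(infl.pos_threshold),
                "kr": _fmt(rep.threshold if rep.active else None),
                "sr": _fmt(rep.strength if rep.active else None),
            }
        )
    pd.DataFrame(rows, columns=PARAM_COLUMNS).to_csv(path, index=False)


def _parse(value: str) -> float | None:
    return None if value == "N/A" else float(value)


def read_params(path) -> dict[str, dict[str, float | None]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = {}
    for _, row in df.iterrows():
        out[row["actor"]] = {
            col: _parse(row[col]) for col in PARAM_COLUMNS if col != "actor"
        }
    return out


def params_to_model(
    by_actor: dict[str, dict[str, float | None]],
    neg_slope: float = 0.5,
    pos_slope: float = 0.5,
) -> DyadModel:
    """Build a DyadModel from a parameter table.

    Influence slopes are not part of the reported parameter layout, so
    portrait reconstruction from a table takes them from configuration
    (default 0.5 per active regime).
    """
    def actor_params(actor: str) -> ModelParameters:
        p = by_actor[actor]
        infl = InfluenceFunction(
            neg_threshold=p.get("nth"),
            pos_threshold=p.get("pth"),
            neg_slope=neg_slope if p.get("nth") is not None else 0.0,
            pos_slope=pos_slope if p.get("pth") is not None else 0.0,
        )
        kr, sr = p.get("kr"), p.get("sr")
        rep = (
            RepairTerm(threshold=kr, strength=sr, active=True)
            if kr is not None and sr is not None
            else RepairTerm()
        )
        return ModelParameters(
            actor=actor,
            initial_state=float(p["a2"]),
            inertia=float(p["r2"]),
            influence_from_partner=infl,
            repair=rep,
        )

    return DyadModel(
        therapist=actor_params("therapist"), client=actor_params("client")
    )


def write_ks(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
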