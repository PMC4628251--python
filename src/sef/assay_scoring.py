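"""Reporter-assay positivity calls and cross-species consistency.

A construct is positive in a (tissue, time) cell when the ectopic-corrected
expressing proportion, minus the empty-vector background proportion for the
same cell, reaches the positivity threshold (default 15 %).  Two syntenic
constructs are functionally homologous when they share at least one
positive (tissue, time) cell after synonym mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.15
DEFAULT_SYNONYMS = {"olfactory bulb": "olfactory epithelium"}


@dataclass(frozen=True)
class PositiveCall:
    construct: str
    tissue: str
    time_hpf: int
    adjusted_proportion: float


@dataclass
class AssayConfig:
    threshold: float = DEFAULT_THRESHOLD
    background: pd.DataFrame | None = None  # empty-vector ExpressionTable

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


def _normalize_tissue(t: str) -> str:
    return " ".join(t.strip().lower().split())


def _background_map(background: pd.DataFrame | None) -> dict[tuple[str, int], float]:
    if background is None:
        return {}
    out: dict[tuple[str, int], float] = {}
    for _, row in background.iterrows():
        if row["n_alive"] <= 0:
            continue
        key = (_normalize_tissue(row["tissue"]), int(row["time_hpf"]))
        prop = (row["n_expressing"] - row["n_ectopic"]) / row["n_alive"]
        out[key] = max(out.get(key, 0.0), float(prop))
    return out


def call_positive(
    table: pd.DataFrame, cfg: AssayConfig | None = None
) -> list[PositiveCall]:
    """Positivity calls per (construct, tissue, time).

    adjusted = (n_expressing - n_ectopic) / n_alive - background proportion;
    positive iff adjusted >= threshold.  Rows with n_alive == 0 are skipped
    with a warning; (tissue, time) cells absent from the background default
    to 0 with a notice.
    """
    cfg = cfg or AssayConfig()
    bg = _background_map(cfg.background)
    calls: list[PositiveCall] = []
    warned: set[tuple[str, int]] = set()
    for _, row in table.iterrows():
        n_alive = int(row["n_alive"])
        if n_alive <= 0:
            logger.warning(
                "row %s/%s@%s has no surviving fish; skipped",
                row["construct"],
                row["tissue"],
                row["time_hpf"],
            )
            continue
        key = (_normalize_tissue(row["tissue"]), int(row["time_hpf"]))
        if cfg.background is not None and key not in bg and key not in warned:
            logger.info("no background for %s; assuming 0", key)
            warned.add(key)
        raw = (int(row["n_expressing"]) - int(row["n_ectopic"])) / n_alive
        adjusted = raw - bg.get(key, 0.0)
        if adjusted >= cfg.threshold:
            calls.append(
                PositiveCall(str(row["construct"]), key[0], key[1], adjusted)
            )
    return calls


def _canonical(
    calls: list[PositiveCall] | set[tuple[str, int]],
    synonym_map: dict[str, str] | None,
) -> set[tuple[str, int]]:
    syn = {
        _normalize_tissue(k): _normalize_tissue(v)
        for k, v in (synonym_map or {}).items()
    }
    # make mapping symmetric onto a canonical representative
    canon: dict[str, str] = {}
    for a, b in syn.items():
        rep = min(a, b)
        canon[a] = rep
        canon[b] = rep
    out: set[tuple[str, int]] = set()
    items = (
        [(c.tissue, c.time_hpf) for c in calls]
        if calls and isinstance(next(iter(calls)), PositiveCall)
        else list(calls)
    )
    for tissue, t in items:
        tissue = _normalize_tissue(tissue)
        out.add((canon.get(tissue, tissue), int(t)))
    return out


def cross_species_consistency(
    calls_sp1: list[PositiveCall] | set[tuple[str, int]],
    calls_sp2: list[PositiveCall] | set[tuple[str, int]],
    synonym_map: dict[str, str] | None = None,
) -> set[tuple[str, int]]:
    """Shared positive (tissue, time) cells after synonym mapping.

    A syntenic enhancer pair is functionally homologous iff the returned
    intersection is non-empty.  Symmetric in its two arguments; the default
    synonym map merges olfactory bulb with olfactory epithelium.
    """
    if synonym_map is None:
        synonym_map = DEFAULT_SYNONYMS
    return _canonical(calls_sp1, synonym_map) & _canonical(calls_sp2, synonym_map)


def functionally_homologous(
    calls_sp1, calls_sp2, synonym_map: dict[str, str] | None = None
) -> bool:
    return bool(cross_species_consistency(calls_sp1, calls_sp2, synonym_map))
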