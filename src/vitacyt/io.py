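"""Readers, writers, and the end-to-end pipeline driver.

Event-level data is read either from CSV tables (comma-separated, header
required, UTF-8, '.' decimal) with columns fsc, ssc, sytobc, cy5 and optional
truth_label, or from FCS 3.0/3.1 list-mode files via the minimal reader in
this module (float or double data, little- or big-endian; a channel-name map
translates instrument channel names to the canonical fsc/ssc/sytobc/cy5).
Abundance tables are TSV with taxa as rows and a header row of sample IDs;
count tables are renormalised to relative abundance per sample.

``run_pipeline`` composes gate -> quantify -> EI -> stats over the inputs a
:class:`PipelineConfig` declares, writes result TSVs (each carrying the config
hash in a header comment line), and emits a JSON run manifest. Identical
config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vitacyt.gating import (
    EVENT_COLUMNS,
    EventTable,
    GateConfig,
    StainRunResult,
    derive_eub338_threshold,
    gate_run,
)
from vitacyt.quantify import BeadSpec, DilutionSeries, LoadResult, quantify_series
from vitacyt.ei import SortedFractionTable, ei_table
from vitacyt.stats import correlation_network

CANONICAL_CHANNELS = EVENT_COLUMNS

# ---------------------------------------------------------------------------
# Minimal FCS 3.0/3.1 list-mode support
# ---------------------------------------------------------------------------


def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read a list-mode FCS 3.0/3.1 file into a DataFrame (one column per
    channel, named by $PnN). Supports $DATATYPE F/D and both byte orders."""
    raw = Path(path).read_bytes()
    version = raw[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise ValueError(f"malformed FCS at offset 0: unsupported version {version!r}")
    try:
        text_begin = int(raw[10:18])
        text_end = int(raw[18:26])
        data_begin = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError as exc:
        raise ValueError("malformed FCS at offset 10: bad header offsets") from exc

    text = raw[text_begin:text_end + 1].decode("utf-8", errors="replace")
    if not text:
        raise ValueError(f"malformed FCS at offset {text_begin}: empty TEXT segment")
    delim = text[0]
    tokens = text[1:].split(delim)
    kv = {tokens[i].strip(): tokens[i + 1] for i in range(0, len(tokens) - 1, 2)}

    if data_begin == 0:
        data_begin = int(kv["$BEGINDATA"])
        data_end = int(kv["$ENDDATA"])
    datatype = kv.get("$DATATYPE", "F")
    if datatype not in ("F", "D"):
        raise ValueError(f"unsupported $DATATYPE {datatype!r}")
    if kv.get("$MODE", "L") != "L":
        raise ValueError("only list mode ($MODE L) is supported")
    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    byteord = kv.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    code = "f" if datatype == "F" else "d"
    width = 4 if datatype == "F" else 8

    payload = raw[data_begin:data_end + 1]
    expected = n_par * n_tot * width
    if len(payload) < expected:
        raise ValueError(f"malformed FCS at offset {data_begin}: "
                         f"DATA segment shorter than $PAR x $TOT")
    values = struct.unpack(f"{endian}{n_par * n_tot}{code}", payload[:expected])
    arr = np.asarray(values, dtype=float).reshape(n_tot, n_par)
    names = [kv.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(arr, columns=names)


def write_fcs(path: str | Path, table: pd.DataFrame) -> None:
    """Write a DataFrame as a minimal FCS 3.0 list-mode file (float32,
    little-endian). Intended for round-trip tests and interoperability checks."""
    channels = list(table.columns)
    data = table.to_numpy(dtype=np.float32)
    n_tot, n_par = data.shape
    payload = data.tobytes(order="C")

    delim = "/"
    keys = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_tot),
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
    }
    for i, name in enumerate(channels, start=1):
        keys[f"$P{i}N"] = str(name)
        keys[f"$P{i}B"] = "32"
        keys[f"$P{i}E"] = "0,0"
        keys[f"$P{i}R"] = str(int(max(1.0, float(np.ceil(data[:, i - 1].max(initial=1.0))))))

    header_len = 58
    # two-pass layout: TEXT length depends on the offsets it records
    for _ in range(3):
        text_begin = header_len
        body = delim + delim.join(f"{k}{delim}{v}" for k, v in keys.items()) + delim
        text_end = text_begin + len(body) - 1
        data_begin = text_end + 1
        data_end = data_begin + len(payload) - 1
        keys["$BEGINDATA"] = str(data_begin)
        keys["$ENDDATA"] = str(data_end)
    header = (
        b"FCS3.0    "
        + f"{text_begin:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + (f"{data_begin:>8d}" if data_begin <= 99_999_999 else f"{0:>8d}").encode()
        + (f"{data_end:>8d}" if data_end <= 99_999_999 else f"{0:>8d}").encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    Path(path).write_bytes(header + body.encode() + payload)


# ---------------------------------------------------------------------------
# Event and abundance tables
# ---------------------------------------------------------------------------


def read_event_table(
    path: str | Path,
    channel_map: dict[str, str] | None = None,
) -> EventTable:
    """Read an event table from CSV or FCS into an :class:`EventTable`.

    ``channel_map`` maps source column/channel names to the canonical names
    (fsc, ssc, sytobc, cy5); unmapped canonical names must already be present.
    """
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        df = read_fcs(path)
    else:
        df = pd.read_csv(path)
    if channel_map:
        df = df.rename(columns=channel_map)
    missing = [c for c in CANONICAL_CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"missing channel {missing[0]}")
    keep = [c for c in (*CANONICAL_CHANNELS, "truth_label") if c in df.columns]
    return EventTable(events=df[keep].reset_index(drop=True))


def write_event_csv(path: str | Path, events: EventTable) -> None:
    events.events.to_csv(path, index=False)


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Read a taxa x samples TSV; renormalise count columns to sum to 1.

    Columns already summing to 1 (within 1e-9) are left unchanged.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"parse error in {path}: {exc}") from exc
    body = df.to_numpy(dtype=float)
    if (body < 0).any():
        raise ValueError("negative abundance value")
    sums = body.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("sample column sums to zero")
    needs_norm = np.abs(sums - 1.0) > 1e-9
    body[:, needs_norm] = body[:, needs_norm] / sums[needs_norm]
    return pd.DataFrame(body, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WellInput:
    path: str
    dilution_factor: float
    run_id: str = ""


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative inputs for one pipeline run. Any stage whose inputs are
    absent is skipped; at least one stage must be runnable."""

    out_dir: str
    wells: tuple[WellInput, ...] = ()
    control_path: str | None = None
    gate: GateConfig = field(default_factory=GateConfig)
    beads: BeadSpec = field(default_factory=BeadSpec)
    channel_map: dict | None = None
    pos_table: str | None = None
    neg_table: str | None = None
    rates_table: str | None = None
    min_prevalence: float = 0.5
    zero_mode: str = "per_taxon"
    cohort_table: str | None = None
    stats_variables: tuple[str, ...] = ()
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "wells" in raw:
            raw["wells"] = tuple(WellInput(**w) for w in raw["wells"])
        if "gate" in raw:
            g = dict(raw["gate"])
            if "bead_gate" in g:
                g["bead_gate"] = tuple(tuple(b) for b in g["bead_gate"])
            raw["gate"] = GateConfig(**g)
        if "beads" in raw:
            raw["beads"] = BeadSpec(**raw["beads"])
        if "stats_variables" in raw:
            raw["stats_variables"] = tuple(raw["stats_variables"])
        return cls(**raw)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_tsv(path: str | Path, df: pd.DataFrame, chash: str,
              index: bool = True) -> None:
    """Write a result TSV with the config hash in a header comment line."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_result_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def gate_wells(
    wells: list[tuple[float, EventTable]],
    control: EventTable,
    config: GateConfig,
    run_prefix: str = "well",
) -> DilutionSeries:
    """Gate a set of stained wells against one control run into a
    :class:`DilutionSeries`."""
    threshold = derive_eub338_threshold(control, config)
    runs = tuple(
        gate_run(ev, threshold, config, dilution_factor=d,
                 run_id=f"{run_prefix}_{i}")
        for i, (d, ev) in enumerate(sorted(wells, key=lambda w: w[0]))
    )
    return DilutionSeries(runs=runs)


def _check_exists(path: str | None) -> None:
    if path is not None and not Path(path).exists():
        raise FileNotFoundError(f"config references absent file: {path}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all runnable stages and write results plus a run manifest.

    Returns a dict with the in-memory results per stage. Any stage failure is
    re-raised with the stage name and offending input attached.
    """
    for p in (config.control_path, config.pos_table, config.neg_table,
              config.rates_table, config.cohort_table,
              *(w.path for w in config.wells)):
        _check_exists(p)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    results: dict = {}
    outputs: list[str] = []

    if config.wells:
        if config.control_path is None:
            raise ValueError("stage gate: wells given but no control run")
        try:
            control = read_event_table(config.control_path, config.channel_map)
            wells = [
                (w.dilution_factor, read_event_table(w.path, config.channel_map))
                for w in config.wells
            ]
            series = gate_wells(wells, control, config.gate)
            load: LoadResult = quantify_series(series, config.beads)
        except Exception as exc:
            raise RuntimeError(f"stage gate/quantify failed: {exc}") from exc
        runs_df = pd.DataFrame([dataclasses.asdict(r) for r in series.runs])
        write_tsv(out_dir / "stain_runs.tsv", runs_df, chash, index=False)
        load_df = pd.DataFrame([{
            "microbial_load": load.microbial_load,
            "log10_microbial_load": np.log10(max(load.microbial_load, 1.0)),
            "living_rate": load.living_rate,
            "viable_load": load.viable_load,
            "log10_viable_load": np.log10(max(load.viable_load, 1.0)),
            "selected_dilution": load.selected_dilution,
            "qc_flags": ";".join(sorted(load.qc_flags)),
        }])
        write_tsv(out_dir / "load_result.tsv", load_df, chash, index=False)
        outputs += ["stain_runs.tsv", "load_result.tsv"]
        results["series"] = series
        results["load"] = load

    if config.pos_table and config.neg_table and config.rates_table:
        try:
            pos_ab = read_abundance_table(config.pos_table)
            neg_ab = read_abundance_table(config.neg_table)
            rates = pd.read_csv(config.rates_table, sep="\t", index_col=0).iloc[:, 0]
            rates = rates.reindex(pos_ab.columns)
            pos = SortedFractionTable(abundance=pos_ab, fraction_label="eub_pos",
                                      fraction_frequency=rates)
            neg = SortedFractionTable(abundance=neg_ab, fraction_label="eub_neg",
                                      fraction_frequency=1.0 - rates)
            ei = ei_table(pos, neg, config.min_prevalence, config.zero_mode)
        except Exception as exc:
            raise RuntimeError(f"stage ei failed: {exc}") from exc
        write_tsv(out_dir / "ei_table.tsv", ei.ei, chash)
        sidecar = {
            "included_taxa": list(ei.included_taxa),
            "replaced_zero_value": {t: float(v)
                                    for t, v in ei.replaced_zero_value.items()},
            "min_prevalence": config.min_prevalence,
            "zero_mode": config.zero_mode,
        }
        (out_dir / "ei_provenance.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True))
        outputs += ["ei_table.tsv", "ei_provenance.json"]
        results["ei"] = ei

    if config.cohort_table and config.stats_variables:
        try:
            cohort = pd.read_csv(config.cohort_table, sep="\t", index_col=0)
            net = correlation_network(cohort, list(config.stats_variables),
                                      config.alpha)
        except Exception as exc:
            raise RuntimeError(f"stage stats failed: {exc}") from exc
        write_tsv(out_dir / "network_edges.tsv", net.edges, chash, index=False)
        outputs.append("network_edges.tsv")
        results["network"] = net

    if not results:
        raise ValueError("config declares no runnable stage")

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "outputs": sorted(outputs),
        "package_version": _version(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    results["manifest"] = manifest
    return results


def _version() -> str:
    from vitacyt import __version__
    return __version__
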