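"""End-to-end analysis orchestration and Knol–VanderWeele table assembly.

``run_analysis`` drives harmonize → per-EPF complete-case subset →
interaction model → table block for every requested ancestry group ×
EPF, with a run log (per-model N, convergence, small-cell warnings) and
full determinism under a fixed config and seed.

The display layer is a pure function of fitted results: formatting never
recomputes statistics, only rounds them (half-up, two decimals for ORs
and RERI, whole percents) the way the motivating tables print them; the
TSV variant carries full precision so displayed values can be backed out
exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .cohort import EPFS, Cohort, CellCounts, exposure_column
from .harmonize import complete_cases, harmonize_cohort
from .stats import InteractionResult, interaction_analysis

DEFAULT_COVARIATES: tuple[str, ...] = (
    "age",
    "gender",
    "pc1",
    "pc2",
    "pc3",
    "pc4",
    "pc5",
)

#: Printed row labels: (unexposed, adverse) per EPF.
EPF_LABELS: dict[str, tuple[str, str]] = {
    "maternal_warmth": ("High maternal warmth (0)", "Low maternal warmth (1)"),
    "financial_burden": (
        "Low childhood financial burden (0)",
        "High childhood financial burden (1)",
    ),
    "childhood_stress": (
        "Low childhood stress events (0)",
        "High childhood stress events (1)",
    ),
    "father_education": ("High father education (0)", "Low father education (1)"),
    "mother_education": ("High mother education (0)", "Low mother education (1)"),
}

SMALL_CELL_TOTAL = 20


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.425 → 0.43), matching print conventions."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt_est(x: float, ndigits: int = 2) -> str:
    return f"{round_half_up(x, ndigits):.{ndigits}f}"


def fmt_or_ci(est_lo_hi: Sequence[float]) -> str:
    est, lo, hi = est_lo_hi[:3]
    return f"{fmt_est(est)} ({fmt_est(lo)}, {fmt_est(hi)})"


def fmt_cell(cases: int, total: int) -> str:
    """'cases/total (percent)' — the second printed number is the cell total."""
    pct = int(round_half_up(100.0 * cases / total, 0)) if total else 0
    return f"{cases}/{total} ({pct}%)"


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input_path: str | None = None
    groups: tuple[str, ...] = ("EA",)
    epfs: tuple[str, ...] = EPFS
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    pgs_cut: float = 0.75
    warmth_cut: float = 0.25
    n_boot: int = 0
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        for name, cut in (("pgs_cut", self.pgs_cut), ("warmth_cut", self.warmth_cut)):
            if not 0.0 < cut < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {cut}")
        unknown = [e for e in self.epfs if e not in EPFS]
        if unknown:
            raise ValueError(f"unknown EPFs {unknown}; supported: {list(EPFS)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("groups", "epfs", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class KVTable:
    """One group × EPF block of the recommended interaction presentation.

    Header note: the printed column is labeled "N (cases/controls)" but
    the second number is the cell TOTAL (cell totals sum to the block N
    and percent = cases/total); output here says cases/total.
    """

    group: str
    epf: str
    n: int
    cells: CellCounts
    result: InteractionResult

    @classmethod
    def from_result(cls, result: InteractionResult) -> "KVTable":
        return cls(
            group=result.group,
            epf=result.epf,
            n=result.n,
            cells=result.cells,
            result=result,
        )


def run_analysis(
    cohort: Cohort | pd.DataFrame,
    config: RunConfig,
) -> tuple[dict[tuple[str, str], KVTable], list[str]]:
    """Full pipeline over every requested group × EPF.

    Returns the table blocks keyed by ``(group, epf)`` and a run log.
    Blocks whose model cannot be identified (degenerate exposure cell,
    separation) are skipped with a logged warning rather than aborting
    the whole run.  If ``config.out_dir`` is set, per-block TSVs and a
    combined text report are written there.
    """
    config.validate()
    if config.input_path is not None and isinstance(cohort, (str, Path)):
        cohort = Cohort.from_csv(cohort)
    derived = harmonize_cohort(
        cohort, pgs_cut=config.pgs_cut, warmth_cut=config.warmth_cut
    )
    required = {"Y", "G"}
    missing_cols = sorted(
        required - set(derived.columns)
    ) + [c for c in config.covariates if c not in derived.columns]
    if missing_cols:
        raise KeyError(f"cohort schema is missing required columns: {missing_cols}")

    tables: dict[tuple[str, str], KVTable] = {}
    log: list[str] = []
    groups = (
        config.groups
        if "group" in derived.columns
        else ("",)
    )
    for grp in groups:
        sub = derived[derived["group"] == grp] if grp else derived
        log.append(f"group={grp or 'all'}: {len(sub)} records")
        for epf in config.epfs:
            e_col = exposure_column(epf)
            if e_col not in derived.columns:
                log.append(f"  {epf}: no exposure column; skipped")
                continue
            cc = complete_cases(sub, ["Y", "G", e_col, *config.covariates])
            log.append(f"  {epf}: complete-case N = {len(cc)}")
            try:
                res = interaction_analysis(
                    cc,
                    epf,
                    covariates=config.covariates,
                    group=grp,
                    n_boot=config.n_boot,
                    boot_seed=config.seed,
                )
            except (ValueError, RuntimeError) as exc:
                log.append(f"  {epf}: model not fit ({exc})")
                continue
            log.append(
                f"  {epf}: converged in {res.fit.n_iter} iterations, llf = {res.fit.llf:.2f}"
            )
            for key, (cases, total) in res.cells:
                if total < SMALL_CELL_TOTAL:
                    log.append(
                        f"  {epf}: WARNING small cell (G,E)={key} total {total} < {SMALL_CELL_TOTAL}"
                    )
            tables[(grp, epf)] = KVTable.from_result(res)
    if config.out_dir is not None:
        _write_outputs(tables, log, config)
    return tables, log


def format_kv_table(table: KVTable, style: str = "text") -> str:
    """Render one block, rounded for display or full-precision TSV."""
    if style == "tsv":
        return _kv_tsv(table)
    if style != "text":
        raise ValueError(f"style must be 'text' or 'tsv', got {style!r}")
    r = table.result
    lab0, lab1 = EPF_LABELS[table.epf]
    c = table.cells
    lines = [
        f"{table.group + ' ' if table.group else ''}{table.epf} (N = {table.n})",
        "  cells are cases/total (percent); the total column sums to N",
        "  PGS < 75th pct (0)              PGS > 75th pct (1)",
        (
            f"  {lab0}: {fmt_cell(*c.cells[(0, 0)])} 1.00 (reference) | "
            f"{fmt_cell(*c.cells[(1, 0)])} {fmt_or_ci(r.or10)}"
        ),
        (
            f"  {lab1}: {fmt_cell(*c.cells[(0, 1)])} {fmt_or_ci(r.or01)} | "
            f"{fmt_cell(*c.cells[(1, 1)])} {fmt_or_ci(r.or11)}"
        ),
        (
            "  OR of PGS within psychosocial strata: "
            f"E=0: {fmt_or_ci(r.stratum_g_in_e0)}; E=1: {fmt_or_ci(r.stratum_g_in_e1)}"
        ),
        (
            "  OR of the psychosocial factor within genetic strata: "
            f"G=0: {fmt_or_ci(r.stratum_e_in_g0)}; G=1: {fmt_or_ci(r.stratum_e_in_g1)}"
        ),
        (
            f"  Multiplicative scale: {fmt_or_ci(r.multiplicative)}, "
            f"p = {fmt_est(r.multiplicative[3])}"
        ),
        (
            f"  RERI: {fmt_est(r.reri.estimate)} "
            f"({fmt_est(r.reri.ci_low)}, {fmt_est(r.reri.ci_high)}), "
            f"p = {fmt_est(r.reri.p)}"
        ),
    ]
    if r.reri_bootstrap_ci is not None:
        lo, hi = r.reri_bootstrap_ci
        lines.append(f"  RERI bootstrap CI: ({fmt_est(lo)}, {fmt_est(hi)})")
    return "\n".join(lines) + "\n"


def _kv_tsv(table: KVTable) -> str:
    r = table.result
    rows: list[tuple[str, str]] = [("group", table.group), ("epf", table.epf), ("n", repr(table.n))]
    for (g, e), (cases, total) in table.cells:
        rows.append((f"cases_g{g}_e{e}", repr(cases)))
        rows.append((f"total_g{g}_e{e}", repr(total)))
    for name, val in (
        ("or10", r.or10),
        ("or01", r.or01),
        ("or11", r.or11),
        ("stratum_g_in_e0", r.stratum_g_in_e0),
        ("stratum_g_in_e1", r.stratum_g_in_e1),
        ("stratum_e_in_g0", r.stratum_e_in_g0),
        ("stratum_e_in_g1", r.stratum_e_in_g1),
    ):
        est, lo, hi = val
        rows += [(name, repr(est)), (name + "_lo", repr(lo)), (name + "_hi", repr(hi))]
    ratio, lo, hi, p = r.multiplicative
    rows += [
        ("multiplicative", repr(ratio)),
        ("multiplicative_lo", repr(lo)),
        ("multiplicative_hi", repr(hi)),
        ("multiplicative_p", repr(p)),
        ("reri", repr(r.reri.estimate)),
        ("reri_lo", repr(r.reri.ci_low)),
        ("reri_hi", repr(r.reri.ci_high)),
        ("reri_p", repr(r.reri.p)),
    ]
    if r.reri_bootstrap_ci is not None:
        rows += [
            ("reri_boot_lo", repr(r.reri_bootstrap_ci[0])),
            ("reri_boot_hi", repr(r.reri_bootstrap_ci[1])),
        ]
    header = "field\tvalue"
    return "\n".join([header] + [f"{k}\t{v}" for k, v in rows]) + "\n"


def export_additive_effects(result) -> pd.DataFrame:
    """Four exposure-combination ORs plus the RERI line, for replotting.

    Accepts an :class:`InteractionResult` or any object exposing ``or10``,
    ``or01``, ``or11`` as (est, lo, hi) and ``reri``; rows are the joint
    exposure combinations against the doubly unexposed reference.
    """
    reri = result.reri
    if hasattr(reri, "estimate"):
        reri_row = (reri.estimate, reri.ci_low, reri.ci_high)
    else:  # published blocks store (est, lo, hi, p)
        reri_row = tuple(reri[:3])
    rows = [
        ("G=0,E=0", 1.0, None, None),
        ("G=1,E=0", *result.or10),
        ("G=0,E=1", *result.or01),
        ("G=1,E=1", *result.or11),
        ("RERI", *reri_row),
    ]
    return pd.DataFrame(rows, columns=["contrast", "estimate", "ci_low", "ci_high"])


def _write_outputs(
    tables: Mapping[tuple[str, str], KVTable],
    log: Sequence[str],
    config: RunConfig,
) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    combined = []
    for (grp, epf), table in sorted(tables.items()):
        stem = f"{grp or 'all'}_{epf}"
        (out / f"{stem}.tsv").write_text(format_kv_table(table, "tsv"), encoding="utf-8")
        combined.append(format_kv_table(table, "text"))
    (out / "kv_tables.txt").write_text("\n".join(combined), encoding="utf-8")
    (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    (out / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=False), encoding="utf-8"
    )
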