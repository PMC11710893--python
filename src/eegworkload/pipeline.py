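"""End-to-end orchestration: simulate -> preprocess -> spectral + microstate -> stats.

``run_pipeline`` executes the whole chain on a synthetic two-condition
workload scenario and returns a :class:`RunReport` whose tables mirror
the analysis outputs: band-power contrasts (total and electrode-wise),
microstate parameter contrasts, transition-probability contrasts and a
band-power x microstate-parameter correlation table.  A run is
reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .layout import make_layout
from .microstate import (
    MicrostateTemplateSet,
    SegmentationResult,
    aggregate_grand_mean,
    backfit,
    compute_gev,
    extract_gfp_peak_maps,
    label_canonical,
    modified_kmeans,
    temporal_parameters,
    transition_probabilities,
    TopographySet,
)
from .preprocess import Recording, preprocess_chain
from .spectral import DEFAULT_BANDS, band_average, periodogram, total_average_power
from .stats import electrode_wise_contrast, paired_t, pearson
from .synth import SubjectPair, make_canonical_templates, make_workload_scenario

__all__ = ["RunConfig", "RunReport", "run_pipeline", "effect_signs"]

_CLASSES = ("A", "B", "C", "D")


@dataclass
class RunConfig:
    """All knobs of one reproducible pipeline run."""

    n_subjects: int = 12
    seed: int = 0
    block_duration_s: float = 60.0
    n_blocks: int = 2
    fs: float = 250.0
    snr_db: float = 10.0
    lo_hz: float = 1.0
    hi_hz: float = 40.0
    notch_hz: float = 50.0
    epoch_length_s: float = 2.0
    reject_uv: float = 100.0
    k: int = 4
    restarts: int = 20
    fit_at: str = "all"
    fdr_q: float = 0.05
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Tables produced by one pipeline run, plus provenance."""

    band_contrasts: pd.DataFrame
    electrode_contrasts: pd.DataFrame
    microstate_params: pd.DataFrame
    microstate_contrasts: pd.DataFrame
    transition_contrasts: pd.DataFrame
    correlations: pd.DataFrame
    template_quality: dict[str, float]
    provenance: dict

    _TABLES = (
        "band_contrasts",
        "electrode_contrasts",
        "microstate_params",
        "microstate_contrasts",
        "transition_contrasts",
        "correlations",
    )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(
                out / f"{name}.csv", index=False, float_format="%.12g"
            )
        summary = {
            "template_quality": self.template_quality,
            "provenance": self.provenance,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


def _preprocess_subject(
    subj: SubjectPair, cfg: RunConfig
) -> tuple[dict[str, list[np.ndarray]], pd.DataFrame]:
    """Preprocess all blocks; returns continuous per-block data and band powers."""
    per_cond: dict[str, list[np.ndarray]] = {}
    band_rows = []
    for cond, blocks in subj.recordings.items():
        per_cond[cond] = []
        for rec in blocks:
            eps = preprocess_chain(
                rec,
                target_fs=cfg.fs,
                lo=cfg.lo_hz,
                hi=cfg.hi_hz,
                notch=cfg.notch_hz,
                epoch_length_s=cfg.epoch_length_s,
                reject_uv=cfg.reject_uv,
            )
            band_rows.append(
                band_average(periodogram(eps), DEFAULT_BANDS, meta=rec.meta)
            )
            per_cond[cond].append(eps.concatenate())
    return per_cond, pd.concat(band_rows, ignore_index=True)


def _epoch_boundaries(n_samples: int, fs: float, epoch_length_s: float) -> list[int]:
    step = int(round(fs * epoch_length_s))
    return list(range(0, n_samples, step))


def _subject_templates(
    per_cond: dict[str, list[np.ndarray]], cfg: RunConfig, layout, seed: int
) -> MicrostateTemplateSet:
    """Pool GFP-peak maps over all conditions/blocks and cluster them."""
    maps, gfps = [], []
    for blocks in per_cond.values():
        for data in blocks:
            rec = Recording(data=data, fs=cfg.fs, layout=layout)
            peaks = extract_gfp_peak_maps(
                rec, _epoch_boundaries(len(data), cfg.fs, cfg.epoch_length_s)
            )
            maps.append(peaks.maps)
            gfps.append(peaks.gfp_values)
    pooled = TopographySet(
        maps=np.concatenate(maps), gfp_values=np.concatenate(gfps)
    )
    tset, _, _ = modified_kmeans(
        pooled, k=cfg.k, n_restarts=cfg.restarts, seed=seed
    )
    return tset


def _segment_condition(
    blocks: list[np.ndarray],
    templates: MicrostateTemplateSet,
    cfg: RunConfig,
    layout,
) -> tuple[SegmentationResult, Recording, list[SegmentationResult]]:
    """Backfit blocks concatenated per condition; also return per-block views."""
    data = np.concatenate(blocks)
    boundaries: list[int] = []
    block_edges = [0]
    offset = 0
    for b in blocks:
        boundaries.extend(
            offset + s for s in _epoch_boundaries(len(b), cfg.fs, cfg.epoch_length_s)
        )
        offset += len(b)
        block_edges.append(offset)
    rec = Recording(data=data, fs=cfg.fs, layout=layout)
    seg = backfit(rec, templates, boundaries=boundaries, fit_at=cfg.fit_at)
    per_block = []
    for a, b in zip(block_edges[:-1], block_edges[1:]):
        inner = [s - a for s in boundaries if a <= s < b]
        per_block.append(
            SegmentationResult(
                labels=seg.labels[a:b],
                abs_corr=seg.abs_corr[a:b],
                gfp=seg.gfp[a:b],
                fs=cfg.fs,
                n_classes=templates.k,
                boundaries=tuple(inner),
            )
        )
    return seg, rec, per_block


def _paired_frame(
    table: pd.DataFrame, value: str, key_cols: list[str]
) -> pd.DataFrame:
    """Wide (subject x condition) frame of ``value`` for each key combination."""
    return table.pivot_table(
        index="subject", columns=["condition"] + key_cols, values=value
    )


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full scenario pipeline; see module docstring."""
    layout = make_layout()
    subjects = make_workload_scenario(
        cfg.n_subjects,
        cfg.seed,
        block_duration_s=cfg.block_duration_s,
        n_blocks=cfg.n_blocks,
        fs=cfg.fs,
        snr_db=cfg.snr_db,
        layout=layout,
    )
    canon = make_canonical_templates(layout)
    rng = np.random.default_rng(cfg.seed)

    band_tables = []
    subject_sets = []
    per_subject_data: list[dict[str, list[np.ndarray]]] = []
    for subj in subjects:
        per_cond, bands = _preprocess_subject(subj, cfg)
        band_tables.append(bands)
        subject_sets.append(
            _subject_templates(
                per_cond, cfg, layout, seed=int(rng.integers(2**31 - 1))
            )
        )
        per_subject_data.append(per_cond)
    band_table = pd.concat(band_tables, ignore_index=True)

    grand = aggregate_grand_mean(subject_sets, seed=cfg.seed)
    grand, quality = label_canonical(grand, canon)

    # --- microstate parameters per subject x condition (+ per block) ----
    ms_rows, block_rows, trans_rows = [], [], []
    for subj, per_cond in zip(subjects, per_subject_data):
        for cond, blocks in per_cond.items():
            seg, rec, per_block = _segment_condition(blocks, grand, cfg, layout)
            params = temporal_parameters(seg)
            gev = compute_gev(seg, rec, grand)
            trans = transition_probabilities(seg)
            for ci, cl in enumerate(_CLASSES[: cfg.k]):
                ms_rows.append(
                    {
                        "subject": subj.subject,
                        "condition": cond,
                        "class": cl,
                        "duration_ms": params.duration_ms[ci],
                        "occurrence_per_s": params.occurrence_per_s[ci],
                        "coverage": params.coverage[ci],
                        "gev": gev,
                    }
                )
            for i in range(cfg.k):
                for j in range(cfg.k):
                    if i != j:
                        trans_rows.append(
                            {
                                "subject": subj.subject,
                                "condition": cond,
                                "from": _CLASSES[i],
                                "to": _CLASSES[j],
                                "prob": trans.probs[i, j],
                            }
                        )
            for bi, bseg in enumerate(per_block):
                bparams = temporal_parameters(bseg)
                brec = Recording(data=blocks[bi], fs=cfg.fs, layout=layout)
                bgev = compute_gev(bseg, brec, grand)
                for ci, cl in enumerate(_CLASSES[: cfg.k]):
                    block_rows.append(
                        {
                            "subject": subj.subject,
                            "condition": cond,
                            "block": bi,
                            "class": cl,
                            "duration_ms": bparams.duration_ms[ci],
                            "occurrence_per_s": bparams.occurrence_per_s[ci],
                            "coverage": bparams.coverage[ci],
                            "gev": bgev,
                        }
                    )
    ms_table = pd.DataFrame(ms_rows)
    ms_block_table = pd.DataFrame(block_rows)
    trans_table = pd.DataFrame(trans_rows)

    # --- contrasts ------------------------------------------------------
    totals = total_average_power(band_table)
    band_rows_out = []
    for band in sorted(totals["band"].unique()):
        sub = totals[totals["band"] == band].set_index(["subject", "condition"])
        low = sub.loc[(slice(None), "low"), "total_power"].to_numpy()
        high = sub.loc[(slice(None), "high"), "total_power"].to_numpy()
        res = paired_t(low, high)  # sign convention: negative t = higher in high
        band_rows_out.append(
            {
                "band": band,
                "mean_low": low.mean(),
                "mean_high": high.mean(),
                "diff_high_minus_low": high.mean() - low.mean(),
                "t": res.t,
                "p": res.p,
                "d": res.d,
            }
        )
    band_contrasts = pd.DataFrame(band_rows_out)

    electrode_tables = []
    for band in sorted(band_table["band"].unique()):
        etab = electrode_wise_contrast(band_table, band, q=cfg.fdr_q)
        etab.insert(0, "band", band)
        electrode_tables.append(etab)
    electrode_contrasts = pd.concat(electrode_tables, ignore_index=True)

    ms_rows_out = []
    for measure in ("duration_ms", "occurrence_per_s", "coverage"):
        for cl in _CLASSES[: cfg.k]:
            sub = ms_table[ms_table["class"] == cl].set_index(
                ["subject", "condition"]
            )
            low = sub.loc[(slice(None), "low"), measure].to_numpy()
            high = sub.loc[(slice(None), "high"), measure].to_numpy()
            res = paired_t(low, high)
            ms_rows_out.append(
                {
                    "measure": measure,
                    "class": cl,
                    "mean_low": low.mean(),
                    "mean_high": high.mean(),
                    "diff_high_minus_low": high.mean() - low.mean(),
                    "t": res.t,
                    "p": res.p,
                    "d": res.d,
                }
            )
    gev_sub = ms_table[ms_table["class"] == "A"].set_index(["subject", "condition"])
    low = gev_sub.loc[(slice(None), "low"), "gev"].to_numpy()
    high = gev_sub.loc[(slice(None), "high"), "gev"].to_numpy()
    res = paired_t(low, high)
    ms_rows_out.append(
        {
            "measure": "gev",
            "class": "all",
            "mean_low": low.mean(),
            "mean_high": high.mean(),
            "diff_high_minus_low": high.mean() - low.mean(),
            "t": res.t,
            "p": res.p,
            "d": res.d,
        }
    )
    microstate_contrasts = pd.DataFrame(ms_rows_out)

    trans_rows_out = []
    for i in _CLASSES[: cfg.k]:
        for j in _CLASSES[: cfg.k]:
            if i == j:
                continue
            sub = trans_table[
                (trans_table["from"] == i) & (trans_table["to"] == j)
            ].set_index(["subject", "condition"])
            low = sub.loc[(slice(None), "low"), "prob"].to_numpy()
            high = sub.loc[(slice(None), "high"), "prob"].to_numpy()
            res = paired_t(low, high)
            trans_rows_out.append(
                {
                    "from": i,
                    "to": j,
                    "mean_low": low.mean(),
                    "mean_high": high.mean(),
                    "diff_high_minus_low": high.mean() - low.mean(),
                    "t": res.t,
                    "p": res.p,
                    "d": res.d,
                }
            )
    transition_contrasts = pd.DataFrame(trans_rows_out)

    # --- correlations: band power vs microstate params per block --------
    block_power = band_table.groupby(
        ["subject", "condition", "block", "band"], as_index=False
    )["power"].mean()
    corr_rows = []
    keys = ["subject", "condition", "block"]
    for band in sorted(block_power["band"].unique()):
        bp = block_power[block_power["band"] == band].set_index(keys)["power"]
        for measure in ("duration_ms", "occurrence_per_s", "coverage"):
            for cl in _CLASSES[: cfg.k]:
                mp = ms_block_table[ms_block_table["class"] == cl].set_index(keys)[
                    measure
                ]
                joined = pd.concat([bp, mp], axis=1).dropna()
                res = pearson(
                    joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
                )
                corr_rows.append(
                    {
                        "band": band,
                        "measure": measure,
                        "class": cl,
                        "R": res.R,
                        "p": res.p,
                        "n": res.n,
                        "strength": res.strength,
                    }
                )
    correlations = pd.DataFrame(corr_rows)

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    provenance = {
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "version": __version__,
    }
    report = RunReport(
        band_contrasts=band_contrasts,
        electrode_contrasts=electrode_contrasts,
        microstate_params=ms_table,
        microstate_contrasts=microstate_contrasts,
        transition_contrasts=transition_contrasts,
        correlations=correlations,
        template_quality=quality,
        provenance=provenance,
    )
    if cfg.out_dir:
        report.write(cfg.out_dir)
    return report


def effect_signs(report: RunReport) -> dict[str, bool]:
    """Planted workload effect directions recovered by a run (high vs low)."""
    bc = report.band_contrasts.set_index("band")["diff_high_minus_low"]
    mc = report.microstate_contrasts.set_index(["measure", "class"])[
        "diff_high_minus_low"
    ]
    tc = report.transition_contrasts.set_index(["from", "to"])[
        "diff_high_minus_low"
    ]
    return {
        "theta_power_up": bc["theta"] > 0,
        "beta_power_up": bc["beta"] > 0,
        "B_duration_down": mc[("duration_ms", "B")] < 0,
        "B_coverage_down": mc[("coverage", "B")] < 0,
        "D_occurrence_up": mc[("occurrence_per_s", "D")] > 0,
        "D_coverage_up": mc[("coverage", "D")] > 0,
        "AB_transitions_down": (tc[("A", "B")] < 0) and (tc[("B", "A")] < 0),
        "CD_transitions_up": (tc[("C", "D")] > 0) and (tc[("D", "C")] > 0),
    }
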