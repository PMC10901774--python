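"""Spike-in normalization, Hit Strength, and the dose-response hit gate.

Hit Strength (HS) is the fold change between a sequence's spike-in-normalized
count at the highest bait concentration and its normalized count in the blank
(no-bait) wells, each averaged across replicates.  A blank raw count of zero
is replaced by 0.5 *before* dividing by that blank's spike-in count, so HS is
always finite.  The dose-response gate asks for a monotone rise of the
per-concentration-level mean normalized count with concentration, scored as a
Spearman rank correlation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .decode import CountMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HitCallParams:
    pseudocount: float = 0.5
    hs_min: float = 5.0
    min_rho: float = 0.8
    min_reads: int = 5


@dataclass
class NormalizedCounts:
    """Per-sample spike-in-normalized abundances (reads per spike-in read)."""

    values: pd.DataFrame          # peptide x valid samples
    spike_counts: pd.Series       # spike counts of valid samples
    invalid_samples: list[str]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def normalize(counts: CountMatrix) -> NormalizedCounts:
    """Divide each sample's counts by its spike-in count.

    A sample with zero spike-in reads cannot be normalized; it is excluded
    and logged.  Normalized values are invariant under any uniform per-sample
    scaling of the raw counts (spike included).
    """
    valid = [s for s in counts.samples if counts.spike_counts[s] > 0]
    invalid = [s for s in counts.samples if counts.spike_counts[s] == 0]
    if invalid:
        logger.warning("excluding samples with zero spike-in counts: %s", invalid)
    values = counts.counts[valid] / counts.spike_counts[valid].astype(float)
    return NormalizedCounts(values, counts.spike_counts[valid], invalid)


def _check_samples(samples: pd.DataFrame, norm: NormalizedCounts) -> pd.DataFrame:
    keep = samples.loc[[s for s in samples.index if s in norm.samples]]
    if keep.empty:
        raise ValueError("no valid samples remain after spike-in filtering")
    return keep


def hit_strength(counts: CountMatrix, norm: NormalizedCounts,
                 samples: pd.DataFrame, pseudocount: float = 0.5) -> pd.Series:
    """Per-peptide Hit Strength.

    Numerator: mean normalized count over highest-concentration replicates.
    Denominator: mean over blank replicates of (raw count, zeros replaced by
    ``pseudocount``) / (that blank's spike-in count).
    """
    samples = _check_samples(samples, norm)
    blanks = samples.index[samples["role"] == "blank"]
    baits = samples[samples["role"] == "bait"]
    if len(blanks) == 0:
        raise ValueError("no valid blank samples")
    if len(baits) == 0:
        raise ValueError("no valid bait samples")
    c_max = baits["concentration_nM"].max()
    top = baits.index[baits["concentration_nM"] == c_max]

    num = norm.values[top].mean(axis=1)
    blank_raw = counts.counts[blanks].astype(float)
    blank_raw = blank_raw.mask(blank_raw == 0, pseudocount)
    blank_norm = blank_raw / norm.spike_counts[blanks].astype(float)
    den = blank_norm.mean(axis=1)
    return num / den


def dose_response(norm: NormalizedCounts, samples: pd.DataFrame,
                  min_rho: float = 0.8) -> pd.DataFrame:
    """Spearman correlation of per-level mean normalized counts with
    concentration.

    Levels are the distinct concentrations including blank (0).  Ties are
    mid-ranked; a peptide whose level means are all equal gets statistic 0.
    With fewer than three levels the gate is not evaluable: every peptide
    passes with statistic NaN and a warning is logged.
    """
    samples = _check_samples(samples, norm)
    levels = sorted(samples["concentration_nM"].unique())
    if len(levels) < 3:
        logger.warning(
            "dose-response needs >=3 concentration levels, got %d; "
            "gate degrades to Hit Strength only", len(levels)
        )
        return pd.DataFrame(
            {"dose_response_stat": np.nan, "passes_dose_response": True},
            index=norm.values.index,
        )
    level_means = pd.DataFrame(
        {
            c: norm.values[samples.index[samples["concentration_nM"] == c]]
            .mean(axis=1)
            for c in levels
        }
    )
    x = rankdata(levels)
    m = level_means.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, m) if len(m) else m
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        xc = x - x.mean()
        rc = ranks - ranks.mean(axis=1, keepdims=True)
        denom = np.sqrt((rc ** 2).sum(axis=1) * (xc ** 2).sum())
        rho = np.where(denom > 0, (rc @ xc) / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.DataFrame(
        {"dose_response_stat": rho, "passes_dose_response": rho >= min_rho},
        index=norm.values.index,
    )


def call_hits(counts: CountMatrix, samples: pd.DataFrame,
              params: HitCallParams | None = None) -> pd.DataFrame:
    """Full hit table: normalized counts, HS, dose-response, and flags.

    A peptide is a hit iff HS >= hs_min, the dose-response gate passes, and
    its best raw count across highest-concentration replicates reaches
    min_reads.  The spike-in row is reported (its HS is exactly 1) but never
    a hit.
    """
    params = params or HitCallParams()
    norm = normalize(counts)
    samples = _check_samples(samples, norm)
    hs = hit_strength(counts, norm, samples, params.pseudocount)
    dr = dose_response(norm, samples, params.min_rho)

    baits = samples[samples["role"] == "bait"]
    top = baits.index[baits["concentration_nM"] == baits["concentration_nM"].max()]
    top_reads = counts.counts[top].max(axis=1)

    table = pd.DataFrame(index=counts.counts.index)
    for s in norm.samples:
        table[f"count_{s}"] = counts.counts[s]
    for s in norm.samples:
        table[f"norm_{s}"] = norm.values[s]
    table["hit_strength"] = hs
    table["dose_response_stat"] = dr["dose_response_stat"]
    table["passes_hs"] = hs >= params.hs_min
    table["passes_dose_response"] = dr["passes_dose_response"]
    table["passes_min_reads"] = top_reads >= params.min_reads
    table["is_hit"] = (
        table["passes_hs"]
        & table["passes_dose_response"]
        & table["passes_min_reads"]
    )

    # spike-in row: HS is 1 by construction, excluded from hit calling
    spike_row = {f"count_{s}": counts.spike_counts[s] for s in norm.samples}
    spike_row.update({f"norm_{s}": 1.0 for s in norm.samples})
    spike_row.update(
        hit_strength=1.0, dose_response_stat=0.0, passes_hs=False,
        passes_dose_response=False, passes_min_reads=False, is_hit=False,
    )
    table.loc[counts.spike_in_label] = pd.Series(spike_row)
    table.index.name = "peptide"
    return table


def write_hit_table(table: pd.DataFrame, path: str | Path,
                    params: HitCallParams | None = None) -> None:
    """Write the hit table TSV plus a JSON sidecar echoing the thresholds."""
    path = Path(path)
    table.to_csv(path, sep="\t", float_format="%.6g")
    if params is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(asdict(params), indent=2, sort_keys=True)
                           + "\n")


def hits(table: pd.DataFrame) -> pd.DataFrame:
    """The subset of the hit table flagged as hits."""
    return table[table["is_hit"].astype(bool)]
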