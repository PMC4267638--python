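"""Wild-type/mutant score pairs -> score variations -> feature rows.

Each splice-site prediction tool emits one score for the wild-type allele
and one for the mutant allele of a variant.  The change caused by the
variant is summarized as up to two *score variations*:

* relative = (wt - mut) / wt, defined whenever the wild-type score is
  non-zero.  A zero wild-type score means the tool failed to recognize the
  true splice site, so the value is treated as missing data, not an error.
* absolute = (wt - mut) / (hi - lo), defined only for tools whose score has
  a finite range (undefined for log-odds scores).

The difference is signed, wt - mut, so loss of splice-site signal is
positive; signal gains come out negative and are left for the downstream
classifier to weigh.

Tools whose missing-score rate exceeds a threshold (default 5%) are screened
out before any feature table is built.  The retained-tool feature order is
frozen (``FEATURE_NAMES_7`` / ``FEATURE_NAMES_11``) so serialized models
stay portable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = float("nan")

#: Frozen feature order for the seven score variations.
FEATURE_NAMES_7 = (
    "pwm_rel",
    "pwm_abs",
    "mes_rel",
    "nnsplice_rel",
    "nnsplice_abs",
    "hsf_rel",
    "hsf_abs",
)
#: Conservation / whole-genome functional scores appended in the 11-feature set.
EXTRA_NAMES = (
    "phylop_placental",
    "phylop_primate",
    "cadd_raw",
    "cadd_phred",
)
FEATURE_NAMES_11 = FEATURE_NAMES_7 + EXTRA_NAMES

#: Which tool and variation kind backs each of the seven features.
FEATURE_TOOLS_7 = (
    ("pwm", "relative"),
    ("pwm", "absolute"),
    ("mes", "relative"),
    ("nnsplice", "relative"),
    ("nnsplice", "absolute"),
    ("hsf", "relative"),
    ("hsf", "absolute"),
)


@dataclass(frozen=True)
class ScoredAllelePair:
    """One tool's wild-type and mutant scores for one variant."""

    tool_id: str
    wt_score: float
    mut_score: float
    score_range: tuple | None = None

    def __post_init__(self):
        if self.score_range is not None:
            lo, hi = self.score_range
            if not lo < hi:
                raise ValueError(f"degenerate score range ({lo}, {hi})")


@dataclass(frozen=True)
class ScoreVariation:
    """Relative and absolute score variations for one tool/variant.

    ``relative`` is NaN when the wild-type score was zero (missing);
    ``absolute`` is None when the tool has no finite score range (undefined),
    NaN when missing.
    """

    tool_id: str
    relative: float
    absolute: float | None

    @property
    def is_missing(self) -> bool:
        return bool(np.isnan(self.relative))


@dataclass(frozen=True)
class ToolScreenReport:
    tool_id: str
    n_missing: int
    n_total: int
    missing_rate: float
    retained: bool


@dataclass
class FeatureRow:
    """One variant's ordered feature vector plus optional binary label."""

    id: str
    features: np.ndarray  # ordered, NaN = missing
    label: int | None = None
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] not in (7, 11):
            raise ValueError(
                f"feature count must be 7 or 11, got {self.features.shape[0]}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def feature_names(self):
        return FEATURE_NAMES_7 if len(self.features) == 7 else FEATURE_NAMES_11


def score_variation(pair: ScoredAllelePair) -> ScoreVariation:
    """Transform a wild-type/mutant score pair into the two variations."""
    d = pair.wt_score - pair.mut_score
    if pair.wt_score == 0:
        relative = MISSING
    else:
        relative = d / pair.wt_score
    if pair.score_range is None:
        absolute = None
    elif pair.wt_score == 0:
        absolute = MISSING
    else:
        lo, hi = pair.score_range
        absolute = d / (hi - lo)
    return ScoreVariation(pair.tool_id, relative, absolute)


def screen_tools(pairs_by_tool: dict, threshold: float = 0.05) -> list:
    """Per-tool missing-rate report; a tool is retained iff rate <= threshold.

    ``pairs_by_tool`` maps tool_id -> iterable of ScoredAllelePair (or, for
    pre-tabulated data, a ``(n_missing, n_total)`` tuple).
    """
    if not pairs_by_tool:
        raise ValueError("no tools supplied")
    reports = []
    for tool_id, pairs in pairs_by_tool.items():
        if isinstance(pairs, tuple) and len(pairs) == 2:
            n_missing, n_total = pairs
        else:
            pairs = list(pairs)
            n_total = len(pairs)
            n_missing = sum(1 for p in pairs if p.wt_score == 0)
        if n_total <= 0:
            raise ValueError(f"tool {tool_id!r} has no observations")
        rate = n_missing / n_total
        reports.append(
            ToolScreenReport(tool_id, n_missing, n_total, rate, rate <= threshold)
        )
    return reports


def build_feature_row(
    variations,
    extra_scores=None,
    label: int | None = None,
    id: str = "",
    **coords,
) -> FeatureRow:
    """Assemble the frozen-order 7- or 11-feature vector for one variant.

    ``variations`` must contain exactly one ScoreVariation per retained tool
    (pwm, mes, nnsplice, hsf); ``extra_scores`` optionally appends the four
    conservation/functional scores.  Missing variations propagate as NaN
    cells — rows are never dropped here.
    """
    by_tool = {}
    for v in variations:
        if v.tool_id in by_tool:
            raise ValueError(f"duplicate tool id {v.tool_id!r}")
        by_tool[v.tool_id] = v
    expected = {t for t, _ in FEATURE_TOOLS_7}
    unknown = set(by_tool) - expected
    if unknown:
        raise ValueError(f"unknown tool id(s): {sorted(unknown)}")
    if set(by_tool) != expected:
        raise ValueError(f"expected tools {sorted(expected)}, got {sorted(by_tool)}")
    values = []
    for tool, kind in FEATURE_TOOLS_7:
        v = by_tool[tool]
        if kind == "relative":
            values.append(v.relative)
        else:
            if v.absolute is None:
                raise ValueError(f"tool {tool!r} has no finite range: absolute undefined")
            values.append(v.absolute)
    if extra_scores is not None:
        extra = [MISSING if e is None else float(e) for e in extra_scores]
        if len(extra) != 4:
            raise ValueError("exactly 4 extra scores expected")
        values.extend(extra)
    return FeatureRow(id=id, features=np.array(values, dtype=float), label=label, **coords)


# -- TSV feature-table dialect ----------------------------------------------

_META_COLS = ["id", "chrom", "pos", "ref", "alt"]


def rows_to_frame(rows) -> pd.DataFrame:
    rows = list(rows)
    if not rows:
        raise ValueError("no rows")
    names = list(rows[0].feature_names)
    recs = []
    for r in rows:
        if list(r.feature_names) != names:
            raise ValueError("mixed 7- and 11-feature rows")
        rec = {
            "id": r.id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
        }
        rec.update(dict(zip(names, r.features)))
        rec["label"] = r.label
        recs.append(rec)
    return pd.DataFrame(recs, columns=_META_COLS + names + ["label"])


def frame_to_rows(df: pd.DataFrame) -> list:
    names = FEATURE_NAMES_11 if EXTRA_NAMES[0] in df.columns else FEATURE_NAMES_7
    rows = []
    for _, rec in df.iterrows():
        label = rec.get("label")
        label = None if pd.isna(label) else int(label)
        rows.append(
            FeatureRow(
                id=str(rec.get("id", "")),
                features=rec[list(names)].to_numpy(dtype=float),
                label=label,
                chrom=None if pd.isna(rec.get("chrom")) else str(rec["chrom"]),
                pos=None if pd.isna(rec.get("pos")) else int(rec["pos"]),
                ref=None if pd.isna(rec.get("ref")) else str(rec["ref"]),
                alt=None if pd.isna(rec.get("alt")) else str(rec["alt"]),
            )
        )
    return rows


def write_feature_table(rows, path) -> None:
    """Write rows as TSV; '.' encodes missing cells."""
    df = rows_to_frame(rows)
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_feature_table(path) -> list:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    return frame_to_rows(df)
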