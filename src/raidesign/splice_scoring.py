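"""Splice-site scoring with position weight matrices (PWMs).

The guideline's splice-site reliability scores come from deep-learning
predictors that are outside the scope of this package.  Here a documented
PWM stands in for them: log-odds against a uniform background, min-max
normalised per window so that the consensus context scores exactly 1.0
and the least likely context 0.0.  Every score carries a ``source`` tag
(``pwm`` or ``external``) so that externally computed predictor scores,
ingested from TSV, can replace the proxy wherever both exist — the
relative-drop rule (<1 % pass, 1-4 % warn, >=4 % fail) is defined on
whichever scorer produced the pair.

Donor model: 3 exonic + 6 intronic positions seeded from the canonical
mammalian consensus MAG|GTRAGT.  Acceptor model: a 20-nt polypyrimidine
tract, the intronic CAG consensus, and one exonic G (CAG|G), 24 nt total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC degeneracies used when seeding matrices from a consensus
_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "M": "AC", "R": "AG", "Y": "CT"}

VALID_CONDITIONS = {"WT", "rAI", "rAI+R"}


@dataclass(frozen=True)
class SpliceSiteScore:
    """A scored splice site.  ``position`` is the cut coordinate: for donors
    the exon|intron boundary, for acceptors the intron|exon boundary."""

    position: int | None
    site_type: str  # donor | acceptor
    score: float
    source: str = "pwm"  # pwm | external
    coord_system: str | None = None  # spliced | genomic
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.site_type not in {"donor", "acceptor"}:
            raise ValueError(f"bad site_type {self.site_type!r}")


@dataclass(frozen=True)
class PwmModel:
    """Position weight matrix over a fixed window around the splice cut.

    ``matrix`` holds per-position base probabilities (rows sum to 1);
    scores are min-max normalised log-odds, so 1.0 is attained exactly by
    per-position maximum-likelihood bases and 0.0 by minimum-likelihood.
    """

    site_type: str
    exonic_len: int
    intronic_len: int
    matrix: np.ndarray  # shape (window, 4), probabilities

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.window, 4):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != ({self.window}, 4)"
            )
        if not np.allclose(self.matrix.sum(axis=1), 1.0):
            raise ValueError("matrix rows must each sum to 1")

    @property
    def window(self) -> int:
        return self.exonic_len + self.intronic_len

    def window_bounds(self, cut_position: int) -> tuple[int, int]:
        """[start, end) of the scoring window around a cut position."""
        if self.site_type == "donor":
            return cut_position - self.exonic_len, cut_position + self.intronic_len
        return cut_position - self.intronic_len, cut_position + self.exonic_len

    def _logodds(self) -> np.ndarray:
        return np.log2(self.matrix / 0.25)

    def raw_score(self, window_seq: str) -> float:
        lo = self._logodds()
        return float(
            sum(lo[i, _BASE_INDEX[b]] for i, b in enumerate(window_seq))
        )

    def normalized_score(self, window_seq: str) -> float:
        lo = self._logodds()
        total = self.raw_score(window_seq)
        lo_min = float(lo.min(axis=1).sum())
        lo_max = float(lo.max(axis=1).sum())
        return min(1.0, max(0.0, (total - lo_min) / (lo_max - lo_min)))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, columns=list(BASES))
        df.insert(0, "position", range(-self.exonic_len, self.intronic_len)
                  if self.site_type == "donor"
                  else range(-self.intronic_len, self.exonic_len))
        df.to_csv(path, sep="\t", index=False)


def _columns_from_consensus(consensus: str, pseudo: float = 0.03) -> np.ndarray:
    rows = []
    for sym in consensus:
        allowed = _IUPAC[sym]
        row = np.full(4, pseudo)
        share = (1.0 - pseudo * (4 - len(allowed))) / len(allowed)
        for b in allowed:
            row[_BASE_INDEX[b]] = share
        rows.append(row)
    return np.array(rows)


def build_default_pwms() -> tuple[PwmModel, PwmModel]:
    """Default donor and acceptor PWMs seeded from the canonical consensus.

    Donor: MAG|GTRAGT (M and R split equally, small pseudocount elsewhere).
    Acceptor: 20 polypyrimidine positions (C/T 0.4 each), intronic CAG,
    one exonic G.
    """
    donor = PwmModel("donor", exonic_len=3, intronic_len=6,
                     matrix=_columns_from_consensus("MAG" + "GTRAGT"))
    ppt = np.tile(
        np.array([0.1, 0.4, 0.1, 0.4]), (20, 1)
    )  # A C G T: pyrimidine-weighted
    cag_g = _columns_from_consensus("CAGG")
    acceptor = PwmModel("acceptor", exonic_len=1, intronic_len=23,
                        matrix=np.vstack([ppt, cag_g]))
    return donor, acceptor


def score_site(model: PwmModel, seq: str, cut_position: int,
               coord_system: str = "spliced") -> SpliceSiteScore:
    """Normalised PWM score of the window around ``cut_position`` in ``seq``."""
    start, end = model.window_bounds(cut_position)
    if start < 0 or end > len(seq):
        raise ValueError(
            f"scoring window [{start}, {end}) outside sequence of length {len(seq)}"
        )
    window = seq[start:end]
    if any(b not in _BASE_INDEX for b in window):
        raise ValueError(f"non-ACGT base in scoring window {window!r}")
    return SpliceSiteScore(
        position=cut_position,
        site_type=model.site_type,
        score=model.normalized_score(window),
        source="pwm",
        coord_system=coord_system,
    )


def scan_sites(model: PwmModel, seq: str, threshold: float,
               coord_system: str = "spliced") -> list[SpliceSiteScore]:
    """All cut positions whose window scores >= threshold, sorted by position."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    lo = (model.exonic_len if model.site_type == "donor" else model.intronic_len)
    hi = len(seq) - (model.intronic_len if model.site_type == "donor"
                     else model.exonic_len)
    hits = []
    for cut in range(lo, hi + 1):
        try:
            s = score_site(model, seq, cut, coord_system)
        except ValueError:
            continue  # window contains N or other non-ACGT base
        if s.score >= threshold:
            hits.append(s)
    return hits


@dataclass(frozen=True)
class ScoreDelta:
    """Relative drop between a before/after score pair, in percent.

    Negative values mean the site improved.  The verdict bands follow the
    tolerated-drop evidence: <1 % pass, 1-4 % warn, >=4 % fail.
    """

    before: SpliceSiteScore
    after: SpliceSiteScore
    drop_percent: float
    verdict: str


def score_delta(before: SpliceSiteScore, after: SpliceSiteScore,
                pass_below: float = 1.0, fail_at: float = 4.0) -> ScoreDelta:
    if before.site_type != after.site_type:
        raise ValueError(
            f"cannot compare {before.site_type} with {after.site_type} scores"
        )
    if before.score == 0:
        raise ValueError("before-score is zero; relative drop undefined")
    drop = 100.0 * (before.score - after.score) / before.score
    if drop < pass_below:
        verdict = "pass"
    elif drop < fail_at:
        verdict = "warn"
    else:
        verdict = "fail"
    return ScoreDelta(before, after, drop, verdict)


def ingest_external_scores(tsv_source) -> dict[tuple[str, str, str], SpliceSiteScore]:
    """Read externally computed splice-site scores from TSV.

    Expected columns: ``site_label``, ``site_type`` (donor|acceptor),
    ``condition`` (WT | rAI | rAI+R), ``score`` in [0, 1].  Returns a
    mapping keyed by (site_label, site_type, condition); external scores
    take precedence over PWM scores wherever both exist.
    """
    try:
        df = pd.read_csv(tsv_source, sep="\t")
    except pd.errors.EmptyDataError:
        return {}
    if df.empty and df.columns.size == 0:
        return {}
    required = {"site_label", "site_type", "condition", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"external score TSV lacks columns {sorted(missing)}")
    mapping: dict[tuple[str, str, str], SpliceSiteScore] = {}
    for row in df.itertuples(index=False):
        if row.condition not in VALID_CONDITIONS:
            raise ValueError(f"bad condition {row.condition!r}")
        score = float(row.score)
        if not 0.0 <= score <= 1.0:
            raise ValueError(
                f"score {score} for {row.site_label!r} outside [0, 1]"
            )
        key = (str(row.site_label), str(row.site_type), str(row.condition))
        mapping[key] = SpliceSiteScore(
            position=None,
            site_type=str(row.site_type),
            score=score,
            source="external",
            label=str(row.site_label),
        )
    return mapping
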