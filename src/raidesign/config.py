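"""Rule thresholds for rAI placement, splicing checks and NMD classification.

Every numeric threshold used by the rule engine lives here.  Where the
guideline gives a range (150/200 bp exon, 500-1000 nt from the polyA,
55/100 nt from the exon 3' end) the conservative bound is the hard (fail)
threshold and the permissive bound is the warn boundary.  The NMD
classifier uses the NMDetective-B values (50 / 150 / 407 nt), which are
kept as knobs distinct from the placement thresholds (55-400 nt window,
200 nt start-proximal) because they come from different rules.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass(frozen=True)
class RuleConfig:
    # --- exon selection -----------------------------------------------------
    min_exon_len: int = 150          # nt; hard minimum exon length
    preferred_exon_len: int = 200    # nt; below this -> warn
    start_codon_exclusion: int = 200  # nt; insertion must sit this far 3' of ATG
    polyA_min_distance: int = 500    # nt (spliced) exon 3' end -> polyA hard bound
    polyA_preferred_distance: int = 1000  # nt; below this -> warn
    # --- within-exon position ----------------------------------------------
    five_prime_exclusion: int = 100  # nt from exon 5' end
    three_prime_exclusion: int = 55  # nt from exon 3' end (hard)
    three_prime_preferred: int = 100  # nt from exon 3' end (warn below)
    ptc_window_min: int = 55         # nt; PTC-to-junction window (inclusive)
    ptc_window_max: int = 400        # nt; PTC-to-junction window (inclusive)
    long_exon_threshold: int = 400   # nt; placement-rule long-exon bound
    # --- NMDetective-B classifier -------------------------------------------
    nmdetective_long_exon: int = 407      # nt
    nmdetective_start_proximal: int = 150  # nt
    nmdetective_penultimate_tail: int = 50  # nt
    # --- degradation --------------------------------------------------------
    long_utr3_threshold: int = 800   # nt; strict > for the long-3'UTR flag
    weight_targeted: float = 0.6     # composite degradation-score weights
    weight_long_utr3: float = 0.25
    weight_in_window: float = 0.15
    # --- splice-score deltas ------------------------------------------------
    score_drop_pass: float = 1.0     # %; drop below this passes
    score_drop_fail: float = 4.0     # %; drop at/above this fails
    cryptic_donor_threshold: float = 0.8  # PWM score to flag a cryptic donor
    # --- donor design -------------------------------------------------------
    cut_site_max_distance: int = 10  # bp; guide cut to insertion gap
    arm_len_up: int = 55             # nt; HDR homology arms
    arm_len_down: int = 56

    def __post_init__(self) -> None:
        for f in fields(self):
            if isinstance(getattr(self, f.name), (int, float)) and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if self.ptc_window_min >= self.ptc_window_max:
            raise ValueError("ptc_window_min must be < ptc_window_max")
        if self.score_drop_pass >= self.score_drop_fail:
            raise ValueError("score_drop_pass must be < score_drop_fail")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    @classmethod
    def from_file(cls, path) -> "RuleConfig":
        """Read a YAML mapping of threshold overrides; unset keys keep defaults."""
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**overrides)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
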