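"""Core record types for clone-level rDNA datasets.

A dataset is a collection of cloned marker sequences (one PCR clone each),
every clone tracing back to an individual specimen collected at a sampling
site. The types here carry that provenance chain (sequence -> specimen ->
site) which the downstream taxonomy is built on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

#: Characters allowed in a normalized nucleotide string.
VALID_ALPHABET = frozenset("ACGTN-")

#: IUPAC ambiguity codes collapsed to N on normalization.
AMBIGUITY_CODES = frozenset("RYSWKMBDHV")


@dataclass(frozen=True)
class SequenceRecord:
    """One clone sequence with specimen/site provenance."""

    sequence_id: str
    specimen_id: str
    site_id: str
    nucleotides: str
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.nucleotides:
            raise ValueError(f"sequence {self.sequence_id!r} has empty nucleotides")
        bad = set(self.nucleotides) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.sequence_id!r} contains invalid characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class Site:
    """A sampling locality with decimal-degree coordinates.

    Longitude follows the (-180, 180] convention.
    """

    site_id: str
    name: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"site {self.site_id!r}: latitude {self.latitude} out of [-90, 90]")
        if not -180.0 < self.longitude <= 180.0:
            raise ValueError(
                f"site {self.site_id!r}: longitude {self.longitude} out of (-180, 180]"
            )


def normalize_nucleotides(raw: str, sequence_id: str = "?") -> str:
    """Upper-case a nucleotide string and collapse ambiguity codes to N.

    Codes other than A/C/G/T/N/- (R, Y, S, W, K, M, B, D, H, V) are replaced
    by N with a logged warning; any other character raises.
    """
    seq = raw.upper()
    if set(seq) & AMBIGUITY_CODES:
        n_amb = sum(seq.count(c) for c in AMBIGUITY_CODES)
        logger.warning(
            "sequence %s: %d ambiguity code(s) normalized to N", sequence_id, n_amb
        )
        seq = "".join("N" if c in AMBIGUITY_CODES else c for c in seq)
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(f"sequence {sequence_id!r}: invalid characters {sorted(bad)}")
    return seq


@dataclass
class Dataset:
    """A validated bundle of sequences, metadata and sites."""

    records: list[SequenceRecord]
    sites: dict[str, Site]
    n_sequences: int = field(init=False)
    n_specimens: int = field(init=False)
    n_sites: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_sequences = len(self.records)
        self.n_specimens = len({r.specimen_id for r in self.records})
        self.n_sites = len({r.site_id for r in self.records})


def validate_dataset(
    records: list[SequenceRecord],
    metadata: dict[str, tuple[str, str]],
    sites: dict[str, Site] | None = None,
    require_coordinates: bool = True,
) -> Dataset:
    """Join sequences with their metadata and check referential integrity.

    Parameters
    ----------
    records : sequences as read from FASTA (provenance fields may be blank).
    metadata : mapping sequence_id -> (specimen_id, site_id).
    sites : site table; if None, ``require_coordinates`` must be False.

    Returns a :class:`Dataset` whose records carry specimen and site ids.
    Raises on orphan sequences, unknown site ids, or an empty record list.
    """
    if not records:
        raise ValueError("dataset is empty: no sequence records")
    orphans = [r.sequence_id for r in records if r.sequence_id not in metadata]
    if orphans:
        raise ValueError(f"sequences without metadata: {orphans}")
    joined = []
    for r in records:
        specimen_id, site_id = metadata[r.sequence_id]
        joined.append(replace(r, specimen_id=specimen_id, site_id=site_id))
    if require_coordinates:
        if sites is None:
            raise ValueError("site table required when coordinates are requested")
        missing = sorted({r.site_id for r in joined} - set(sites))
        if missing:
            raise ValueError(f"sites referenced but absent from site table: {missing}")
    ds = Dataset(records=joined, sites=dict(sites or {}))
    logger.info(
        "validated dataset: %d sequences, %d specimens, %d sites",
        ds.n_sequences, ds.n_specimens, ds.n_sites,
    )
    return ds
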