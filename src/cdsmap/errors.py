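"""Exception hierarchy shared across the package."""


class CdsmapError(Exception):
    """Base class for all fatal errors raised by cdsmap."""


class ReferenceFileError(CdsmapError):
    """A reference input (FASTA, GTF, genetic-code table) is missing or malformed."""


class IndexFileError(CdsmapError):
    """A coding-sequence index file is missing, truncated or inconsistent."""


class RegionFileError(CdsmapError):
    """A batch region-list file is malformed beyond per-row recovery."""
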