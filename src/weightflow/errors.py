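"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration field is missing or out of range."""


class ValidationError(ValueError):
    """Input data violates a schema or precondition."""


class DataIntegrityError(ValueError):
    """Cross-table references are inconsistent (orphan ids, missing rows)."""


class UnresolvedEntriesError(ValueError):
    """Reviewer disagreement without a consensus verdict."""

    def __init__(self, entry_ids):
        self.entry_ids = sorted(entry_ids)
        super().__init__(
            f"{len(self.entry_ids)} flagged entries have discordant reviewer "
            f"verdicts and no consensus label: {self.entry_ids[:10]}"
            + ("..." if len(self.entry_ids) > 10 else "")
        )


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""
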