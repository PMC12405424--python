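"""Exception hierarchy shared across the package."""


class DomainError(ValueError):
    """An input violates a documented precondition (range, sign, shape)."""


class SingularDesignError(DomainError):
    """The regression design matrix is rank deficient.

    Carries the indices and names of the deficient columns so the caller
    can see which polynomial terms are not identifiable from the data.
    """

    def __init__(self, deficient_columns, column_names):
        self.deficient_columns = list(deficient_columns)
        self.column_names = list(column_names)
        cols = ", ".join(self.column_names) if self.column_names else "unknown"
        super().__init__(
            f"design matrix is rank deficient; non-identifiable columns: {cols}"
        )
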