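"""Shared helpers for the test suite."""

from epimediate.cohort import Cohort


def clone_cohort(cohort: Cohort) -> Cohort:
    return Cohort(
        methylation=cohort.methylation.copy(),
        site_table=cohort.site_table.copy(),
        exposure=cohort.exposure.copy(),
        outcomes=cohort.outcomes.copy(),
        covariates=cohort.covariates.copy(),
        gene_map=cohort.gene_map,
    )
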