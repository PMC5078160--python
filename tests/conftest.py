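import pytest

from fepbench.synthgen import load_fixtures

#: Temperature at which kT = 1 kJ/mol exactly; lets tests state expected
#: values in thermal units.
UNIT_KT = 1.0 / 8.31446e-3


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def table5_components(fixtures):
    from fepbench.qmscore import EnergyComponents

    return [
        EnergyComponents(
            ligand=row.ligand,
            bigqm_ptch=row.bq_ptch,
            bigqm_cosmo=row.bq_cosmo,
            dispersion=row.disp,
            basis_correction=row.bsc,
            g_therm=row.g_therm,
            ligand_relax_printed=row.l_rlx,
            solv_cosmo=row.solv_cosmo,
            solv_cosmors=row.solv_cosmors,
        )
        for row in fixtures.table5.itertuples()
    ]
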