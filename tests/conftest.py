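import math

import pytest

from mzqpost.model import (
    NULL,
    Assay,
    CvParam,
    Feature,
    FeatureList,
    Level,
    PeptideConsensus,
    ProteinRecord,
    QuantDocument,
    QuantLayer,
    StudyVariable,
)
from mzqpost.simulate import SimulationConfig, generate_study

NAN = float("nan")


def tiny_doc() -> QuantDocument:
    """Hand-built two-assay document exercising every element class."""
    doc = QuantDocument()
    doc.assays = [
        Assay(id="a1", name="run one", raw_file_ref="one.raw"),
        Assay(id="a2", name="run, two", raw_file_ref="two.raw"),
    ]
    doc.study_variables = [
        StudyVariable(id="sv1", name="wt", assay_refs=["a1"]),
        StudyVariable(id="sv2", name="ko", assay_refs=["a2"]),
    ]
    doc.feature_lists = [
        FeatureList(
            id="fl1",
            raw_file_ref="one.raw",
            features=[
                Feature(id="f1", mz=500.3, rt=1200.0, rt_window=(1195.0, 1205.0), charge=2),
                Feature(id="f2", mz=620.8, rt=900.0),
            ],
        ),
        FeatureList(
            id="fl2",
            raw_file_ref="two.raw",
            features=[Feature(id="f3", mz=500.31, rt=1201.0, charge=2)],
        ),
    ]
    doc.peptide_list = [
        PeptideConsensus(
            id="pep1",
            sequence="PEPTIDEK",
            modifications=[(3, 15.9949)],
            charge=2,
            feature_refs={"fl1": "f1", "fl2": "f3"},
        ),
        PeptideConsensus(id="pep2", feature_refs={"fl1": "f2"}),
    ]
    doc.protein_list = [ProteinRecord(accession="P1", peptide_refs=["pep1"])]
    doc.quant_layers = [
        QuantLayer(
            id="ql1",
            level=Level.peptide,
            data_type=CvParam("MS:1001893", "peptide raw abundance"),
            column_refs=["a1", "a2"],
            row_refs=["pep1", "pep2"],
            values=[[100.0, 50.0], [NULL, NAN]],
        )
    ]
    return doc


@pytest.fixture
def doc2x2() -> QuantDocument:
    return tiny_doc()


def assay_matrix_doc(values, row_prefix="r", assay_prefix="a",
                     accession="MS:1001893", level=Level.peptide):
    """Document holding one quant layer built from a plain nested list."""
    n_rows = len(values)
    n_cols = len(values[0])
    doc = QuantDocument()
    doc.assays = [Assay(id=f"{assay_prefix}{j}") for j in range(n_cols)]
    row_refs = [f"{row_prefix}{i}" for i in range(n_rows)]
    if level == Level.peptide:
        doc.peptide_list = [
            PeptideConsensus(id=r, sequence=f"SEQ{r.upper()}") for r in row_refs
        ]
    doc.quant_layers = [
        QuantLayer(
            id="ql",
            level=level,
            data_type=CvParam(accession, "abundance"),
            column_refs=[a.id for a in doc.assays],
            row_refs=row_refs,
            values=[[float(v) if isinstance(v, (int, float)) and not (
                isinstance(v, float) and math.isnan(v)) else v for v in row]
                for row in values],
        )
    ]
    return doc


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated study shared across read-only tests."""
    cfg = SimulationConfig(n_proteins=40, n_assays=4, groups=(2, 2), seed=11)
    return generate_study(cfg)
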