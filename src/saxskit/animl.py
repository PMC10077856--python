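"""Typed AnIML document model with XML (de)serialization.

AnIML (Analytical Information Markup Language) is an XML standard for
analytical-chemistry data.  The subset modelled here covers what a 1D SAXS
workflow needs: a ``SampleSet`` of samples, an ``ExperimentStepSet`` where
each step holds the infrastructure (sample references), method metadata and
results (measured series plus analysis categories), and an ``AuditTrailSet``
recording mutations.  Scalar values inside series and parameters are tagged
by kind — ``<I>`` for integers, ``<F>`` for reals, ``<S>`` for text,
``<Boolean>`` for truth values — and the tag is preserved on round trip.

The models are pydantic classes; mutation goes through the document's
``add_*`` methods, which enforce ID uniqueness and referential integrity and
append audit entries.
"""

from __future__ import annotations

from datetime import datetime, timezone
from typing import Literal, Optional, Union

from lxml import etree
from pydantic import BaseModel, Field, field_validator

from .readers import infer_value_tag

__all__ = [
    "SIUnit",
    "Unit",
    "Parameter",
    "Category",
    "Series",
    "SeriesSet",
    "Method",
    "ExperimentStep",
    "Sample",
    "AuditEntry",
    "AnIMLDocument",
    "AnIMLError",
]

Scalar = Union[bool, int, float, str]

ANIML_VERSION = "0.90"


class AnIMLError(ValueError):
    """Raised on AnIML model violations (duplicate IDs, dangling refs, ...)."""


class SIUnit(BaseModel):
    """One SI base-unit component of a derived unit: symbol with factor,
    exponent and offset (label = factor * symbol**exponent + offset)."""

    symbol: str
    factor: float = 1.0
    exponent: float = 1.0
    offset: float = 0.0

    @field_validator("factor")
    @classmethod
    def _factor_nonzero(cls, v: float) -> float:
        if v == 0:
            raise ValueError("SIUnit factor must be non-zero")
        return v


class Unit(BaseModel):
    label: str
    quantity: str = ""
    si_units: list[SIUnit] = Field(default_factory=list)

    @field_validator("label")
    @classmethod
    def _label_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("unit label must be non-empty")
        return v


class Parameter(BaseModel):
    """A named scalar with an optional unit."""

    name: str
    value: Scalar
    unit: Optional[Unit] = None

    @property
    def value_tag(self) -> str:
        return infer_value_tag(self.value)


class Category(BaseModel):
    """A named group of parameters, possibly nested."""

    name: str
    parameters: list[Parameter] = Field(default_factory=list)
    subcategories: list["Category"] = Field(default_factory=list)

    def add_parameter(self, parameter: Parameter) -> None:
        if any(p.name == parameter.name for p in self.parameters):
            raise AnIMLError(
                f"duplicate parameter name {parameter.name!r} "
                f"in category {self.name!r}"
            )
        self.parameters.append(parameter)

    def get_parameter(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(f"no parameter {name!r} in category {self.name!r}")


class Series(BaseModel):
    """A homogeneous list of scalars with dependency and unit metadata."""

    series_id: str
    values: list[Scalar]
    dependency: Literal["dependent", "independent"] = "dependent"
    plot_scale: str = "linear"
    unit: Optional[Unit] = None

    @property
    def value_tag(self) -> str:
        if not self.values:
            return "F"
        tags = {infer_value_tag(v) for v in self.values}
        if len(tags) > 1:
            raise AnIMLError(
                f"series {self.series_id!r} mixes value kinds: {sorted(tags)}"
            )
        return tags.pop()

    @field_validator("values")
    @classmethod
    def _homogeneous(cls, v: list[Scalar]) -> list[Scalar]:
        if v and len({infer_value_tag(x) for x in v}) > 1:
            raise ValueError("series values must be homogeneous in kind")
        return v


class SeriesSet(BaseModel):
    name: str
    series: list[Series] = Field(default_factory=list)

    @field_validator("series")
    @classmethod
    def _equal_lengths(cls, v: list[Series]) -> list[Series]:
        lengths = {len(s.values) for s in v}
        if len(lengths) > 1:
            raise ValueError("all series in a series set must have equal length")
        return v


class Method(BaseModel):
    instrument: str = ""
    authors: list[str] = Field(default_factory=list)
    software: str = ""
    parameters: list[Category] = Field(default_factory=list)


class ExperimentStep(BaseModel):
    """One measurement: sample references, method metadata and results."""

    step_id: str
    name: str = ""
    sample_refs: list[str] = Field(default_factory=list)
    method: Method = Field(default_factory=Method)
    result: list[Union[Category, SeriesSet]] = Field(default_factory=list)

    @field_validator("sample_refs")
    @classmethod
    def _has_samples(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("an experiment step must reference >= 1 sample")
        return v

    def series_iter(self):
        for item in self.result:
            if isinstance(item, SeriesSet):
                yield from item.series


class Sample(BaseModel):
    sample_id: str
    name: str = ""

    @field_validator("sample_id")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("sampleID must be non-empty")
        return v


class AuditEntry(BaseModel):
    author: str = "saxskit"
    timestamp: str = ""
    action: str = ""


def _utc_now() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


class AnIMLDocument(BaseModel):
    """Root container: SampleSet + ExperimentStepSet + AuditTrailSet.

    All mutation should go through :meth:`add_sample`,
    :meth:`add_experiment_step` and :meth:`append_analysis_results`; these
    enforce uniqueness/referential invariants and write audit entries.
    Passing ``timestamp`` pins the audit time (for reproducible output).
    """

    sample_set: list[Sample] = Field(default_factory=list)
    experiment_step_set: list[ExperimentStep] = Field(default_factory=list)
    audit_trail_set: list[AuditEntry] = Field(default_factory=list)

    # -- mutation -----------------------------------------------------------

    def _audit(self, action: str, timestamp: str | None) -> None:
        self.audit_trail_set.append(
            AuditEntry(timestamp=timestamp or _utc_now(), action=action)
        )

    def add_sample(self, sample: Sample, timestamp: str | None = None) -> None:
        if any(s.sample_id == sample.sample_id for s in self.sample_set):
            raise AnIMLError(f"duplicate sampleID {sample.sample_id!r}")
        self.sample_set.append(sample)
        self._audit(f"add_sample {sample.sample_id}", timestamp)

    def add_experiment_step(
        self, step: ExperimentStep, timestamp: str | None = None
    ) -> None:
        known = {s.sample_id for s in self.sample_set}
        dangling = [r for r in step.sample_refs if r not in known]
        if dangling:
            raise AnIMLError(
                f"experiment step {step.step_id!r} references unknown "
                f"samples {dangling}"
            )
        if any(s.step_id == step.step_id for s in self.experiment_step_set):
            raise AnIMLError(f"duplicate experimentStepID {step.step_id!r}")
        existing = set(self.list_series_ids())
        for series in step.series_iter():
            if series.series_id in existing:
                raise AnIMLError(f"duplicate seriesID {series.series_id!r}")
            existing.add(series.series_id)
        self.experiment_step_set.append(step)
        self._audit(f"add_experiment_step {step.step_id}", timestamp)

    def append_analysis_results(
        self,
        step_id: str,
        results: Category,
        strict: bool = True,
        timestamp: str | None = None,
    ) -> None:
        """Append an analysis Category to a step's Result element.

        Keeps analysis output distinct from the measurement data.  If a
        category of the same name already exists, strict mode raises; lenient
        mode stores it under a versioned name (``name (2)``, ``name (3)``...).
        """
        step = self.get_step(step_id)
        names = {c.name for c in step.result if isinstance(c, Category)}
        if results.name in names:
            if strict:
                raise AnIMLError(
                    f"step {step_id!r} already has a category "
                    f"named {results.name!r}"
                )
            base, n = results.name, 2
            while f"{base} ({n})" in names:
                n += 1
            results = results.model_copy(update={"name": f"{base} ({n})"})
        step.result.append(results)
        self._audit(f"append_analysis_results {step_id}/{results.name}", timestamp)

    # -- lookup -------------------------------------------------------------

    def get_step(self, step_id: str) -> ExperimentStep:
        for step in self.experiment_step_set:
            if step.step_id == step_id:
                return step
        raise AnIMLError(f"no experiment step {step_id!r}")

    def list_series_ids(self) -> list[str]:
        return [
            s.series_id
            for step in self.experiment_step_set
            for s in step.series_iter()
        ]

    def get_series(self, series_id: str) -> Series:
        for step in self.experiment_step_set:
            for s in step.series_iter():
                if s.series_id == series_id:
                    return s
        raise KeyError(f"no series {series_id!r} in document")

    def validate_integrity(self) -> None:
        ids = [s.sample_id for s in self.sample_set]
        if len(ids) != len(set(ids)):
            raise AnIMLError("duplicate sampleIDs")
        series_ids = self.list_series_ids()
        if len(series_ids) != len(set(series_ids)):
            raise AnIMLError("duplicate seriesIDs")
        known = set(ids)
        for step in self.experiment_step_set:
            for ref in step.sample_refs:
                if ref not in known:
                    raise AnIMLError(
                        f"dangling sample reference {ref!r} in step "
                        f"{step.step_id!r}"
                    )

    # -- XML ----------------------------------------------------------------

    def to_xml(self) -> str:
        """Serialize to AnIML XML (UTF-8 text)."""
        self.validate_integrity()
        return _to_xml(self)

    @classmethod
    def from_xml(cls, text: str | bytes) -> "AnIMLDocument":
        """Parse AnIML XML produced by :meth:`to_xml` (or compatible)."""
        return _from_xml(text)


# ---------------------------------------------------------------------------
# XML serialization


def _scalar_to_elem(parent: etree._Element, value: Scalar) -> None:
    tag = infer_value_tag(value)
    elem = etree.SubElement(parent, tag)
    if tag == "Boolean":
        elem.text = "true" if value else "false"
    elif tag == "F":
        elem.text = repr(float(value))
    else:
        elem.text = str(value)


def _scalar_from_elem(elem: etree._Element) -> Scalar:
    text = elem.text or ""
    if elem.tag == "I":
        return int(text)
    if elem.tag == "F":
        return float(text)
    if elem.tag == "Boolean":
        return text.strip().lower() == "true"
    if elem.tag == "S":
        return text
    raise AnIMLError(f"unknown value tag <{elem.tag}>")


def _unit_to_elem(parent: etree._Element, unit: Unit) -> None:
    u = etree.SubElement(parent, "Unit", label=unit.label)
    if unit.quantity:
        u.set("quantity", unit.quantity)
    for si in unit.si_units:
        etree.SubElement(
            u,
            "SIUnit",
            factor=repr(si.factor),
            exponent=repr(si.exponent),
            offset=repr(si.offset),
        ).text = si.symbol


def _unit_from_elem(u: etree._Element) -> Unit:
    return Unit(
        label=u.get("label", ""),
        quantity=u.get("quantity", ""),
        si_units=[
            SIUnit(
                symbol=si.text or "",
                factor=float(si.get("factor", "1")),
                exponent=float(si.get("exponent", "1")),
                offset=float(si.get("offset", "0")),
            )
            for si in u.findall("SIUnit")
        ],
    )


def _category_to_elem(parent: etree._Element, cat: Category) -> None:
    c = etree.SubElement(parent, "Category", name=cat.name)
    for p in cat.parameters:
        pe = etree.SubElement(c, "Parameter", name=p.name)
        _scalar_to_elem(pe, p.value)
        if p.unit is not None:
            _unit_to_elem(pe, p.unit)
    for sub in cat.subcategories:
        _category_to_elem(c, sub)


def _category_from_elem(c: etree._Element) -> Category:
    params = []
    for pe in c.findall("Parameter"):
        value_elems = [ch for ch in pe if ch.tag in ("I", "F", "S", "Boolean")]
        if len(value_elems) != 1:
            raise AnIMLError(
                f"parameter {pe.get('name')!r} must hold exactly one value"
            )
        unit_elem = pe.find("Unit")
        params.append(
            Parameter(
                name=pe.get("name", ""),
                value=_scalar_from_elem(value_elems[0]),
                unit=_unit_from_elem(unit_elem) if unit_elem is not None else None,
            )
        )
    return Category(
        name=c.get("name", ""),
        parameters=params,
        subcategories=[_category_from_elem(sc) for sc in c.findall("Category")],
    )


def _series_set_to_elem(parent: etree._Element, ss: SeriesSet) -> None:
    length = len(ss.series[0].values) if ss.series else 0
    e = etree.SubElement(parent, "SeriesSet", name=ss.name, length=str(length))
    for s in ss.series:
        se = etree.SubElement(
            e,
            "Series",
            seriesID=s.series_id,
            seriesType=s.value_tag,
            dependency=s.dependency,
            plotScale=s.plot_scale,
        )
        if s.unit is not None:
            _unit_to_elem(se, s.unit)
        ivs = etree.SubElement(se, "IndividualValueSet")
        for v in s.values:
            _scalar_to_elem(ivs, v)


def _series_from_elem(se: etree._Element) -> Series:
    ivs = se.find("IndividualValueSet")
    values = [_scalar_from_elem(v) for v in ivs] if ivs is not None else []
    unit_elem = se.find("Unit")
    return Series(
        series_id=se.get("seriesID", ""),
        values=values,
        dependency=se.get("dependency", "dependent"),
        plot_scale=se.get("plotScale", "linear"),
        unit=_unit_from_elem(unit_elem) if unit_elem is not None else None,
    )


def _to_xml(doc: AnIMLDocument) -> str:
    root = etree.Element("AnIML", version=ANIML_VERSION)
    sample_set = etree.SubElement(root, "SampleSet")
    for s in doc.sample_set:
        etree.SubElement(sample_set, "Sample", sampleID=s.sample_id, name=s.name)
    step_set = etree.SubElement(root, "ExperimentStepSet")
    for step in doc.experiment_step_set:
        e = etree.SubElement(
            step_set,
            "ExperimentStep",
            experimentStepID=step.step_id,
            name=step.name,
        )
        infra = etree.SubElement(e, "Infrastructure")
        refs = etree.SubElement(infra, "SampleReferenceSet")
        for ref in step.sample_refs:
            etree.SubElement(refs, "SampleReference", sampleID=ref)
        method = etree.SubElement(e, "Method")
        if step.method.instrument:
            etree.SubElement(method, "Instrument").text = step.method.instrument
        for author in step.method.authors:
            etree.SubElement(method, "Author").text = author
        if step.method.software:
            etree.SubElement(method, "Software").text = step.method.software
        for cat in step.method.parameters:
            _category_to_elem(method, cat)
        result = etree.SubElement(e, "Result")
        for item in step.result:
            if isinstance(item, SeriesSet):
                _series_set_to_elem(result, item)
            else:
                _category_to_elem(result, item)
    audit = etree.SubElement(root, "AuditTrailSet")
    for entry in doc.audit_trail_set:
        ae = etree.SubElement(
            audit, "AuditTrailEntry", author=entry.author, timestamp=entry.timestamp
        )
        ae.text = entry.action
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def _from_xml(text: str | bytes) -> AnIMLDocument:
    if isinstance(text, str):
        text = text.encode("utf-8")
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise AnIMLError(f"malformed XML: {exc}")
    if root.tag != "AnIML":
        raise AnIMLError(f"root element is <{root.tag}>, expected <AnIML>")
    doc = AnIMLDocument()
    sample_set = root.find("SampleSet")
    if sample_set is not None:
        for s in sample_set.findall("Sample"):
            doc.sample_set.append(
                Sample(sample_id=s.get("sampleID", ""), name=s.get("name", ""))
            )
    step_set = root.find("ExperimentStepSet")
    if step_set is not None:
        for e in step_set.findall("ExperimentStep"):
            refs = [
                r.get("sampleID", "")
                for r in e.findall("Infrastructure/SampleReferenceSet/SampleReference")
            ]
            method_elem = e.find("Method")
            method = Method()
            if method_elem is not None:
                inst = method_elem.find("Instrument")
                sw = method_elem.find("Software")
                method = Method(
                    instrument=inst.text or "" if inst is not None else "",
                    authors=[a.text or "" for a in method_elem.findall("Author")],
                    software=sw.text or "" if sw is not None else "",
                    parameters=[
                        _category_from_elem(c)
                        for c in method_elem.findall("Category")
                    ],
                )
            result: list[Union[Category, SeriesSet]] = []
            result_elem = e.find("Result")
            if result_elem is not None:
                for item in result_elem:
                    if item.tag == "SeriesSet":
                        result.append(
                            SeriesSet(
                                name=item.get("name", ""),
                                series=[
                                    _series_from_elem(se)
                                    for se in item.findall("Series")
                                ],
                            )
                        )
                    elif item.tag == "Category":
                        result.append(_category_from_elem(item))
                    else:
                        raise AnIMLError(
                            f"unexpected element <{item.tag}> under <Result>"
                        )
            doc.experiment_step_set.append(
                ExperimentStep(
                    step_id=e.get("experimentStepID", ""),
                    name=e.get("name", ""),
                    sample_refs=refs,
                    method=method,
                    result=result,
                )
            )
    audit = root.find("AuditTrailSet")
    if audit is not None:
        for ae in audit.findall("AuditTrailEntry"):
            doc.audit_trail_set.append(
                AuditEntry(
                    author=ae.get("author", ""),
                    timestamp=ae.get("timestamp", ""),
                    action=ae.text or "",
                )
            )
    doc.validate_integrity()
    return doc
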