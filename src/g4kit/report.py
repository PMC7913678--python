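"""Per-oligonucleotide report rendering (HTML canonical, markdown secondary).

Each report carries the metadata header (sequence, origin, topology
annotations, rating) and one panel per technique: CD spectrum, melting curve
with folded fraction, imino-region NMR trace, labeled mass spectrum, and
arrival-time distribution.  Panels are inline SVG drawn with matplotlib;
techniques with no data get an explicit "not available" placeholder.
"""

from __future__ import annotations

import io

import numpy as np
from jinja2 import Environment, PackageLoader, select_autoescape

from . import melting as meltmod
from . import ms as msmod

_env = None


def _get_env() -> Environment:
    global _env
    if _env is None:
        _env = Environment(
            loader=PackageLoader("g4kit", "templates"),
            autoescape=select_autoescape(["html"]),
        )
    return _env


def _fig_to_svg(fig) -> str:
    import matplotlib.pyplot as plt

    buf = io.StringIO()
    fig.savefig(buf, format="svg", bbox_inches="tight")
    plt.close(fig)
    svg = buf.getvalue()
    # strip the XML prolog so the SVG can be inlined
    return svg[svg.index("<svg") :]


def _panel_cd(spec) -> str:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 2.8))
    ylabel = "$\\Delta\\varepsilon$ (M$^{-1}$cm$^{-1}$)" if spec.unit == "delta_epsilon" else "CD (mdeg)"
    ax.plot(spec.wavelength_nm, spec.signal, lw=1.2)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel(ylabel)
    return _fig_to_svg(fig)


def _panel_melting(curve) -> str:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(7.5, 2.8))
    axes[0].plot(curve.temperature_C, curve.absorbance, ".", ms=3)
    axes[0].set_xlabel("temperature (°C)")
    axes[0].set_ylabel(curve.unit)
    try:
        fit = meltmod.fit_two_state(curve)
        if fit.converged and fit.baselines_ok:
            T = np.linspace(curve.temperature_C.min(), curve.temperature_C.max(), 200)
            axes[0].plot(
                T,
                meltmod.two_state_model(
                    T + 273.15, fit.Tm_K, fit.dH0_J_mol,
                    fit.a_F, fit.b_F, fit.a_U, fit.b_U,
                ),
                "r-", lw=1,
            )
            theta = meltmod.folded_fraction(fit, T + 273.15)
            axes[1].plot(T, theta, lw=1.2)
            axes[1].axhline(0.5, color="0.7", lw=0.8)
            axes[1].axvline(fit.Tm_C, color="0.7", lw=0.8)
            axes[1].set_xlabel("temperature (°C)")
            axes[1].set_ylabel("folded fraction θ")
            axes[1].set_title(f"Tm = {fit.Tm_C:.1f} °C", fontsize=9)
    except ValueError:
        axes[1].text(0.5, 0.5, "fit unavailable", ha="center", va="center")
    return _fig_to_svg(fig)


def _panel_nmr(trace) -> str:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from .nmr import IMINO_WINDOW, crop_region

    try:
        shown = crop_region(trace, *IMINO_WINDOW)
    except ValueError:
        shown = trace
    fig, ax = plt.subplots(figsize=(4.2, 2.8))
    ax.plot(shown.ppm, shown.intensity, lw=0.8)
    ax.invert_xaxis()
    ax.set_xlabel("$^1$H chemical shift (ppm)")
    ax.set_ylabel("intensity")
    return _fig_to_svg(fig)


def _panel_ms(spec, sequence: str | None) -> str:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.8, 2.8))
    ax.plot(spec.mz, spec.intensity, lw=0.8)
    ax.set_xlabel("m/z (Th)")
    ax.set_ylabel("intensity")
    if sequence:
        try:
            assigns = msmod.annotate(spec, sequence, charges=(5,))
            top = max((s.matched_intensity for s in assigns), default=0)
            for s in assigns:
                if s.matched_intensity > 0:
                    ax.annotate(
                        s.label,
                        (s.expected_mz, spec.intensity.max() * 0.95),
                        rotation=90, fontsize=7, ha="center",
                    )
        except ValueError:
            pass
    return _fig_to_svg(fig)


def _panel_atd(ims) -> str:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    arr = np.asarray(ims)
    trace = msmod.extract_atd(arr, (arr[:, 1].min() - 1, arr[:, 1].max() + 1),
                              normalize=True)
    fig, ax = plt.subplots(figsize=(4.2, 2.8))
    ax.plot(trace.arrival_time_ms, trace.intensity, lw=1.0)
    ax.set_xlabel("arrival time (ms)")
    ax.set_ylabel("normalized intensity")
    return _fig_to_svg(fig)


def build_report(db, oligo_name: str, fmt: str = "html") -> str:
    """Render the report document for one oligonucleotide as a string."""
    oligo = db.oligos[oligo_name]
    records = [r for r in db.records if r.oligo == oligo_name]
    if not records:
        from .database import DatabaseRecord

        # still render the metadata header plus explicit placeholders
        records = [DatabaseRecord(oligo=oligo_name, condition="(no data)")]

    sections = []
    for rec in records:
        panels = {}
        annotations = rec.datasets.get("panel_annotations") or {}
        for technique, title in [
            ("cd", "Circular dichroism"),
            ("melting", "UV-melting"),
            ("nmr", "1H NMR (imino region)"),
            ("ms", "Native ESI-MS"),
            ("ims", "Arrival time distribution"),
        ]:
            data = rec.datasets.get(technique)
            if data is None:
                panels[technique] = {"title": title, "svg": None}
                continue
            if fmt == "md":
                panels[technique] = {"title": title, "svg": "(figure omitted in markdown)"}
                continue
            drawer = {
                "cd": _panel_cd,
                "melting": _panel_melting,
                "nmr": _panel_nmr,
                "ms": lambda d: _panel_ms(d, oligo.sequence),
                "ims": _panel_atd,
            }[technique]
            panels[technique] = {"title": title, "svg": drawer(data)}
        sections.append(
            {"condition": rec.condition, "panels": panels, "annotations": annotations}
        )

    template = _get_env().get_template(f"report.{fmt}.j2")
    topo = oligo.topology
    return template.render(
        oligo=oligo,
        topology=topo,
        sections=sections,
    )
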