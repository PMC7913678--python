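<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>{{ oligo.name }} — G-quadruplex biophysics report</title>
<style>
body { font-family: sans-serif; margin: 2em; max-width: 70em; }
table.meta td { padding: 0.15em 0.8em 0.15em 0; }
.panel { display: inline-block; vertical-align: top; margin: 0.5em; }
.missing { color: #888; font-style: italic; border: 1px dashed #ccc;
           padding: 2em; }
code { background: #f4f4f4; padding: 0 0.2em; }
</style>
</head>
<body>
<h1>{{ oligo.name }}</h1>
<table class="meta">
  <tr><td>Sequence (5'&rarr;3')</td><td><code>{{ oligo.sequence }}</code> ({{ oligo.sequence|length }} nt)</td></tr>
  <tr><td>Origin</td><td>{{ oligo.origin }}</td></tr>
  <tr><td>Family</td><td>{{ oligo.family or "—" }}</td></tr>
  {% if oligo.pdb_ids %}<tr><td>PDB</td><td>{{ oligo.pdb_ids }}</td></tr>{% endif %}
  {% if topology %}
  <tr><td>Strand orientation</td><td>{{ topology.strand_orientation or "—" }}</td></tr>
  <tr><td>Quartets</td><td>{{ topology.quartet_count if topology.quartet_count is not none else "—" }}</td></tr>
  <tr><td>Stacking</td><td>{{ topology.stacking_type or "—" }}</td></tr>
  <tr><td>Loops</td><td>{{ topology.loops or "—" }}</td></tr>
  <tr><td>Groove widths</td><td>{{ topology.grooves or "—" }}</td></tr>
  {% endif %}
  <tr><td>Rating</td><td>{{ oligo.rating or "unrated" }}</td></tr>
</table>

{% for section in sections %}
<h2>Condition: {{ section.condition }}</h2>
{% if section.annotations %}
<table class="meta">
  {% for key, value in section.annotations.items() %}
  {% if value is not none %}<tr><td>{{ key }}</td><td>{{ value }}</td></tr>{% endif %}
  {% endfor %}
</table>
{% endif %}
{% for technique, panel in section.panels.items() %}
<div class="panel">
<h3>{{ panel.title }}</h3>
{% if panel.svg %}{{ panel.svg|safe }}{% else %}<div class="missing">not available</div>{% endif %}
</div>
{% endfor %}
{% endfor %}
</body>
</html>
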