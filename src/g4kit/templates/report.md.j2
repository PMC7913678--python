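# {{ oligo.name }}

| field | value |
|---|---|
| Sequence (5'->3') | `{{ oligo.sequence }}` ({{ oligo.sequence|length }} nt) |
| Origin | {{ oligo.origin }} |
| Family | {{ oligo.family or "-" }} |
{% if oligo.pdb_ids %}| PDB | {{ oligo.pdb_ids }} |
{% endif %}{% if topology %}| Strand orientation | {{ topology.strand_orientation or "-" }} |
| Quartets | {{ topology.quartet_count if topology.quartet_count is not none else "-" }} |
| Stacking | {{ topology.stacking_type or "-" }} |
| Loops | {{ topology.loops or "-" }} |
| Groove widths | {{ topology.grooves or "-" }} |
{% endif %}| Rating | {{ oligo.rating or "unrated" }} |

{% for section in sections %}
## Condition: {{ section.condition }}

{% for key, value in section.annotations.items() %}{% if value is not none %}- {{ key }}: {{ value }}
{% endif %}{% endfor %}
{% for technique, panel in section.panels.items() %}
### {{ panel.title }}

{% if panel.svg %}{{ panel.svg }}{% else %}not available{% endif %}
{% endfor %}
{% endfor %}
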