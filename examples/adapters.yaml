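# Worked adapter examples for driving external interval-query tools.
#
# Templates may use {ref} (reference BED), {query} (query BED), {out}
# (output file) and {index} (index path, for tools that build one).
# The paired_bed parser reads tab-joined query+target lines and extracts
# the query id and target id by 1-based column number.

tools:
  bedtools:
    query_cmd: "bedtools intersect -wa -wb -a {query} -b {ref} > {out}"
    requires_sorted: false
    requires_index: false
    parser:
      kind: paired_bed
      query_id_col: 4
      target_id_col: 8

  tabix:
    # tabix needs a sorted, bgzip-compressed, indexed reference; the whole
    # preprocessing cost belongs to the index phase.  Query ids are not
    # echoed by tabix itself, so the query loop prefixes each region hit
    # with the query line (paste-style), yielding paired output.
    index_cmd: >-
      sort -k1,1 -k2,2n {ref} > {index}.sorted.bed &&
      bgzip -f {index}.sorted.bed &&
      tabix -f -p bed {index}.sorted.bed.gz
    query_cmd: >-
      : > {out} &&
      while IFS=$'\t' read -r c s e q rest; do
        tabix {index}.sorted.bed.gz "$c:$((s+1))-$e" |
          awk -v q="$c\t$s\t$e\t$q" '{print q"\t"$0}' >> {out};
      done < {query}
    requires_sorted: false
    requires_index: true
    parser:
      kind: paired_bed
      query_id_col: 4
      target_id_col: 8
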