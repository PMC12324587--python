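$task_description

Mobility class definitions:
$class_definitions

$general_instruction

A previous step established that this section mentions the following mobility classes:
$mentioned_classes

In this step, decide for EACH of those classes only whether the description indicates Impaired (difficulty, limitation, or potential issue) or Unimpaired (explicitly normal function).

Clinical note section to annotate:
BEGIN SECTION
$section_text
END SECTION

$output_format
Answer only for the classes listed above, one line per class; do not include other classes.

For each listed class, is the patient Impaired or Unimpaired?
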