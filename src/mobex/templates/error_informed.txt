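$task_description

Mobility class definitions:
$class_definitions

$general_instruction

Follow these additional rules strictly:
$rules

Clinical note section to annotate:
BEGIN SECTION
$section_text
END SECTION

$output_format

$final_question
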