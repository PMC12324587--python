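$task_description

Mobility class definitions:
$class_definitions

$general_instruction

In this step, decide ONLY whether each mobility class is mentioned in the section. Do not judge impairment; a later step will do that. Answer "Mentioned" for a class the section describes in any way, and "None" for a class it does not reference.

Clinical note section to annotate:
BEGIN SECTION
$section_text
END SECTION

$output_format
For this step, use the status "Mentioned" instead of "Impaired" or "Unimpaired" for every mentioned class, and "None" otherwise.

Which mobility classes does this section mention?
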