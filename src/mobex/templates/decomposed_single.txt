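$task_description

Mobility class definitions:
$class_definitions

$general_instruction

Work through the task in two explicit steps:
Step 1. For each of the five mobility classes, decide whether the section contains any description relevant to that class (Mentioned) or not (NotMentioned).
Step 2. For every class you judged Mentioned in Step 1, decide whether the description indicates Impaired (difficulty, limitation, or potential issue) or Unimpaired (explicitly normal function). Classes judged NotMentioned receive None.

Clinical note section to annotate:
BEGIN SECTION
$section_text
END SECTION

After completing both steps, give your final answer.
$output_format

$final_question
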