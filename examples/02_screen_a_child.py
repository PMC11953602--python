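"""Run one adaptive screening session for one child.

Question selection is age-driven: the form holds the child's age-month
questions plus any question failed at the previous session that is still
inside its applicability window.  The decision rule maps failures to a
graded suggestion.
"""

import datetime as dt

from milescreen import (
    Answer,
    ChildProfile,
    ScreeningSession,
    age_in_months,
    decide,
    render_report,
    select_questions,
)
from milescreen.simulate import KbGenConfig, gen_kb

kb = gen_kb(KbGenConfig(seed=7))

child = ChildProfile(
    child_id="demo-004", birth_date=dt.date(2022, 1, 10),
    gender="female", center="nursery_school", gestational_weeks=39.0,
    bilingual=False)

eval_date = dt.date(2023, 3, 15)
age = age_in_months(child.birth_date, eval_date)
asked = select_questions(kb, child, eval_date)
print(f"child age: {age} completed months; form asks {len(asked)} questions")

# answer: fail the last two items, pass the rest
answers = {qid: Answer.yes for qid in asked}
for qid in asked[-2:]:
    answers[qid] = Answer.no

session = ScreeningSession(
    child_id=child.child_id, evaluation_date=eval_date, age_months=age,
    asked=asked, answers=answers)
result = decide(kb, session)
print(f"suggestion: {result.type.value} "
      f"(severity {result.severity_class}; triggered by {result.triggered_by})")

session = session.model_copy(update={"suggestion": result})
report = render_report(child, session, kb, fmt="json")
print(f"follow-up due: {report['follow_up_date']}")
# Two failed warning-class items map to a repeat in 2 months; a single
# failed alarm-class item would instead force direct referral.
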