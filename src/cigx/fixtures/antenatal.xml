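<?xml version='1.0' encoding='UTF-8'?>
<!--
Miniature antenatal guideline: booking gate with one-shot advice,
pre-eclampsia risk alerting (>=140 mmHg systolic with proteinuria;
illustrative configuration, not normative content), gestational-age-keyed
recommendations on the passage of time, and referral to secondary care
once the pre-eclampsia risk flag is set.
-->
<guideline xmlns="urn:cigx:1" id="antenatal_mini" title="Miniature antenatal care guideline" version="1.0">
  <node id="booking" label="Antenatal booking">
    <goal>
      <description>Patient registered for antenatal care</description>
      <conditions>
        <eq>
          <symbol path="pregnancy/registered"/>
          <value type="boolean">true</value>
        </eq>
      </conditions>
    </goal>
    <node id="booking_advice" label="Booking advice">
      <goal>
        <description>one-shot advice under the booking gate</description>
        <conditions>
          <false/>
        </conditions>
      </goal>
      <rule id="visit_plan">
        <precondition trigger="clinical_data_pattern">
          <eq>
            <symbol path="pregnancy/registered"/>
            <value type="boolean">true</value>
          </eq>
        </precondition>
        <action kind="message">
          <payload>antenatal booking confirmed; visit plan issued</payload>
        </action>
      </rule>
    </node>
  </node>
  <node id="risk_evaluation" label="Obstetrical risk evaluation" complete-on-action="true">
    <goal>
      <description>latches once the pre-eclampsia alert has been raised</description>
      <conditions>
        <false/>
      </conditions>
    </goal>
    <rule id="preeclampsia_pattern">
      <precondition trigger="clinical_data_pattern">
        <and>
          <ge>
            <symbol path="exam/bp_systolic"/>
            <value type="integer">140</value>
          </ge>
          <eq>
            <symbol path="labs/urine_protein/present"/>
            <value type="boolean">true</value>
          </eq>
        </and>
      </precondition>
      <action kind="alert">
        <payload>possible pre-eclampsia: hypertension with proteinuria; urgent clinical review</payload>
      </action>
      <action kind="calculation">
        <payload>flag pre-eclampsia risk</payload>
        <assign path="risk/preeclampsia" type="boolean" value="true"/>
      </action>
    </rule>
  </node>
  <node id="gestational_advice" label="Gestational-age-keyed advice">
    <goal>
      <description>schedule-driven advice complete once term is reached</description>
      <conditions>
        <ge>
          <symbol path="pregnancy/gestational_age_weeks"/>
          <value type="integer">39</value>
        </ge>
      </conditions>
    </goal>
    <rule id="ga_11_16">
      <precondition trigger="time_passage">
        <in-range symbol="pregnancy/gestational_age_weeks" type="integer" lower="11" upper="16"/>
      </precondition>
      <action kind="recommendation">
        <payload>offer dating ultrasound and first-trimester screening</payload>
      </action>
    </rule>
    <rule id="ga_18_22">
      <precondition trigger="time_passage">
        <in-range symbol="pregnancy/gestational_age_weeks" type="integer" lower="18" upper="22"/>
      </precondition>
      <action kind="recommendation">
        <payload>schedule fetal anatomy ultrasound</payload>
      </action>
    </rule>
    <rule id="ga_24_28">
      <precondition trigger="time_passage">
        <in-range symbol="pregnancy/gestational_age_weeks" type="integer" lower="24" upper="28"/>
      </precondition>
      <action kind="recommendation">
        <payload>offer oral glucose tolerance test for gestational diabetes</payload>
      </action>
    </rule>
    <rule id="ga_30_34">
      <precondition trigger="time_passage">
        <in-range symbol="pregnancy/gestational_age_weeks" type="integer" lower="30" upper="34"/>
      </precondition>
      <action kind="recommendation">
        <payload>offer Tdap vaccination and assess fetal growth</payload>
      </action>
    </rule>
    <rule id="ga_35_40">
      <precondition trigger="time_passage">
        <in-range symbol="pregnancy/gestational_age_weeks" type="integer" lower="35" upper="40"/>
      </precondition>
      <action kind="recommendation">
        <payload>offer group B streptococcus screening</payload>
      </action>
    </rule>
  </node>
  <node id="referral" label="Care-level referral" complete-on-action="true">
    <goal>
      <description>latches once the referral has been suggested</description>
      <conditions>
        <false/>
      </conditions>
    </goal>
    <rule id="refer_secondary">
      <precondition trigger="clinical_data_pattern">
        <eq>
          <symbol path="risk/preeclampsia"/>
          <value type="boolean">true</value>
        </eq>
      </precondition>
      <action kind="referral">
        <payload>transfer from primary to secondary antenatal care</payload>
      </action>
    </rule>
  </node>
</guideline>
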