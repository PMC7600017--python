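<?xml version="1.0" encoding="UTF-8"?>
<!-- Guideline document dialect (namespace urn:cigx:1).

     A guideline is an ordered hierarchy of nodes.  Each node carries a goal
     (its completion criterion, a boolean condition over the patient state),
     zero or more rules (a triggered precondition guarding one or more
     actions) and zero or more child nodes.  The precondition trigger and
     action kind attributes are closed enumerations.

     A companion top-level <events> element encodes an encounter stream:
     clock advances interleaved with timestamped observations. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:c="urn:cigx:1"
           targetNamespace="urn:cigx:1"
           elementFormDefault="qualified"
           attributeFormDefault="unqualified">

  <xs:include schemaLocation="cigx-expr.xsd"/>

  <xs:simpleType name="triggerKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="time_passage"/>
      <xs:enumeration value="clinical_data_pattern"/>
      <xs:enumeration value="diagnostic_test_value"/>
      <xs:enumeration value="treatment_result"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="actionKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="data_request"/>
      <xs:enumeration value="message"/>
      <xs:enumeration value="alert"/>
      <xs:enumeration value="recommendation"/>
      <xs:enumeration value="calculation"/>
      <xs:enumeration value="medication_order"/>
      <xs:enumeration value="lab_test_request"/>
      <xs:enumeration value="procedure_request"/>
      <xs:enumeration value="referral"/>
      <xs:enumeration value="notification"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="provenanceKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="reported"/>
      <xs:enumeration value="diagnostic_test"/>
      <xs:enumeration value="treatment_result"/>
      <xs:enumeration value="derived"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="guideline" type="c:guidelineType"/>

  <xs:complexType name="guidelineType">
    <xs:sequence>
      <xs:element name="node" type="c:nodeType" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:NCName" use="required"/>
    <xs:attribute name="title" type="xs:string" use="required"/>
    <xs:attribute name="version" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:complexType name="nodeType">
    <xs:sequence>
      <xs:element name="goal" type="c:goalType"/>
      <xs:element name="rule" type="c:ruleType" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="node" type="c:nodeType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:NCName" use="required"/>
    <xs:attribute name="label" type="xs:string"/>
    <xs:attribute name="complete-on-action" type="xs:boolean" default="false"/>
  </xs:complexType>

  <xs:complexType name="goalType">
    <xs:sequence>
      <xs:element name="description" type="xs:string" minOccurs="0"/>
      <xs:element ref="c:conditions"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="ruleType">
    <xs:sequence>
      <xs:element name="precondition" type="c:preconditionType"/>
      <xs:element name="action" type="c:actionType" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:NCName" use="required"/>
  </xs:complexType>

  <xs:complexType name="preconditionType">
    <xs:group ref="c:expr"/>
    <xs:attribute name="trigger" type="c:triggerKind" use="required"/>
  </xs:complexType>

  <xs:complexType name="actionType">
    <xs:sequence>
      <xs:element name="payload" type="xs:string"/>
      <xs:element name="assign" type="c:assignType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="kind" type="c:actionKind" use="required"/>
  </xs:complexType>

  <xs:complexType name="assignType">
    <xs:attribute name="path" type="c:semanticPath" use="required"/>
    <xs:attribute name="type" type="c:valueKind" use="required"/>
    <xs:attribute name="value" type="xs:string" use="required"/>
  </xs:complexType>

  <!-- Encounter event streams (XML form) -->

  <xs:element name="events" type="c:eventsType"/>

  <xs:complexType name="eventsType">
    <xs:choice minOccurs="0" maxOccurs="unbounded">
      <xs:element name="time-advance">
        <xs:complexType>
          <xs:attribute name="at" type="xs:dateTime" use="required"/>
        </xs:complexType>
      </xs:element>
      <xs:element name="observation">
        <xs:complexType>
          <xs:attribute name="timestamp" type="xs:dateTime" use="required"/>
          <xs:attribute name="path" type="c:semanticPath" use="required"/>
          <xs:attribute name="type" type="c:valueKind" use="required"/>
          <xs:attribute name="value" type="xs:string" use="required"/>
          <xs:attribute name="provenance" type="c:provenanceKind" use="required"/>
        </xs:complexType>
      </xs:element>
    </xs:choice>
  </xs:complexType>

</xs:schema>
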